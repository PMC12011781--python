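"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mixsignal as mx


def latin_property_holds(layout) -> bool:
    """Brute-force Latin-property checker: no treatment twice in any row
    or column."""
    seen = layout.iter_plot_treatments()
    plots = layout.plots
    for dim in ("row", "col"):
        for _, sub in plots.groupby(dim):
            ts = [seen[p] for p in sub["plot_id"]]
            if len(ts) != len(set(ts)):
                return False
    return True


def scan_source_plots(layout, mixture_plot: str, pair) -> set:
    """Exhaustive same-row/same-column (or same-block) scan for the
    monoculture source plots of one mixture plot; independent of
    expected_mixture's own discovery logic."""
    plots = layout.plots.set_index("plot_id")
    treatments = layout.iter_plot_treatments()
    me = plots.loc[mixture_plot]
    out = set()
    for pid, t in treatments.items():
        if len(t) != 1 or t[0] not in pair:
            continue
        other = plots.loc[pid]
        if layout.design_kind == "latin_square":
            if other["row"] == me["row"] or other["col"] == me["col"]:
                out.add(pid)
        else:
            if other["block"] == me["block"]:
                out.add(pid)
    return out


@pytest.fixture(scope="session")
def glmm_fixture_data() -> pd.DataFrame:
    """Frozen bioassay dataset used for the external GLMM oracle values."""
    sc = mx.BioassayScenario(receivers=("A", "B"),
                             effect_logit={("A", "B"): -1.0, ("B", "A"): 0.5},
                             baseline_logit=1.0, pot_sd=0.5, seed=42)
    return mx.generate_bioassay(sc)


@pytest.fixture(scope="session")
def meta_fixture_table() -> pd.DataFrame:
    """12-effect table used for the external meta-analysis oracle values."""
    return pd.DataFrame({
        "effect": [-0.52, -0.31, 0.08, -0.45, -0.12, 0.25,
                   -0.6, -0.38, -0.05, 0.15, -0.3, -0.22],
        "se": [0.15, 0.2, 0.25, 0.18, 0.22, 0.3,
               0.16, 0.19, 0.28, 0.24, 0.21, 0.17],
        "year": ["2019", "2020", "2021"] * 4,
        "country": ["P"] * 6 + ["Q"] * 6,
        "crop": ["wheat", "barley"] * 6,
    })


def reml_neg2_oracle(y, X, s2, tau2, codes) -> float:
    """Independent -2 restricted log-likelihood for a single random
    intercept grouping, written from the definition."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    Z = np.eye(int(np.max(codes)) + 1)[np.asarray(codes)]
    V = np.diag(np.asarray(s2, float)) + tau2 * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    _, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(logdetV + logdetX + r @ Vi @ r + (n - p) * np.log(2 * np.pi))
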