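"""Multilevel random-effects meta-analysis of mixture effects.

Each row is one standardized observed-vs-expected coefficient with its
standard error. The marginal model is

    effect_i ~ Normal( (X beta)_i ,  se_i^2 + sum_g tau2_g z-structure )

with crossed random intercepts for the named grouping factors (trial year,
country, crop species), estimated by restricted maximum likelihood. The
fixed part X is an intercept (global model) or indicators of the lab
interaction category (moderator model); moderator coefficients are tested
jointly with a Wald chi-square (QM) statistic. Prediction intervals add
every variance component to the estimate's sampling variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .errors import ModelInputError, NotConvergedError
from .screening import PairClassification

_Z95 = 1.96


def _reml_neg2(y: np.ndarray, X: np.ndarray, s2: np.ndarray,
               ZZt: Sequence[np.ndarray], tau2: np.ndarray) -> float:
    """-2 x restricted log-likelihood of the marginal model at tau2."""
    n, p = X.shape
    V = np.diag(s2).astype(float)
    for t, M in zip(tau2, ZZt):
        V += t * M
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    return logdetV + logdetXtViX + quad + (n - p) * np.log(2 * np.pi)


class MultilevelMeta:
    """Meta-analytic model over an effect table.

    Parameters
    ----------
    table : DataFrame
        Columns ``effect`` and ``se`` plus one column per grouping factor
        (and the moderator column when requested).
    groupings : sequence of str
        Columns entering as crossed random intercepts.
    moderator : str, optional
        Categorical column whose levels form the fixed part.
    coding : {"reference", "cell_means"}
        Reference coding tests the levels-1 contrasts against the first
        level (QM df = levels-1); cell-means coding tests every level mean
        against zero (QM df = levels).
    """

    def __init__(self, table: pd.DataFrame, groupings: Sequence[str] = ("year", "country", "crop"),
                 moderator: Optional[str] = None, coding: str = "reference"):
        if "effect" not in table.columns and "coefficient" in table.columns:
            table = table.rename(columns={"coefficient": "effect"})
        if len(table) < 2:
            raise ModelInputError("meta-analysis needs at least 2 effect rows")
        if (table["se"] <= 0).any():
            bad = table.index[table["se"] <= 0].tolist()
            raise ModelInputError(f"non-positive standard errors in rows {bad}")
        for g in groupings:
            if g not in table.columns:
                raise ModelInputError(f"grouping column {g!r} missing from table")
        if coding not in ("reference", "cell_means"):
            raise ModelInputError(f"unknown coding {coding!r}")
        if moderator is not None and moderator not in table.columns:
            raise ModelInputError(f"moderator column {moderator!r} missing")
        self.table = table.reset_index(drop=True)
        self.groupings = list(groupings)
        self.moderator = moderator
        self.coding = coding
        self.y = self.table["effect"].to_numpy(dtype=float)
        self.s2 = self.table["se"].to_numpy(dtype=float) ** 2

        self._ZZt = []
        for g in self.groupings:
            # empty/NaN levels (e.g. an unlabelled trial) form one level
            codes, _ = pd.factorize(self.table[g].astype(str).fillna(""))
            Z = np.eye(codes.max() + 1)[codes]
            self._ZZt.append(Z @ Z.T)

        if moderator is None:
            self.levels = []
            self.X = np.ones((len(self.table), 1))
            self.param_names = ["intercept"]
        else:
            self.levels = sorted(self.table[moderator].astype(str).unique())
            codes = self.table[moderator].astype(str).map(
                {lv: i for i, lv in enumerate(self.levels)}).to_numpy()
            D = np.eye(len(self.levels))[codes]
            if coding == "cell_means":
                self.X = D
                self.param_names = list(self.levels)
            else:
                self.X = np.column_stack([np.ones(len(codes)), D[:, 1:]])
                self.param_names = ["intercept"] + [f"{lv} - {self.levels[0]}"
                                                   for lv in self.levels[1:]]

    # -- estimation --------------------------------------------------------

    def reml_criterion(self, tau2: Sequence[float]) -> float:
        """-2 restricted log-likelihood at fixed variance components."""
        return _reml_neg2(self.y, self.X, self.s2, self._ZZt,
                          np.asarray(tau2, dtype=float))

    def _mom_start(self) -> float:
        """DerSimonian-Laird-style total-heterogeneity starting value."""
        w = 1.0 / self.s2
        Xw = self.X * w[:, None]
        beta = np.linalg.solve(self.X.T @ Xw, Xw.T @ self.y)
        r = self.y - self.X @ beta
        q = float(w @ r ** 2)
        df = len(self.y) - self.X.shape[1]
        denom = w.sum() - (w ** 2).sum() / w.sum()
        return max(0.0, (q - df) / denom) if denom > 0 else 0.0

    def fit(self, fix_tau2: Optional[Mapping[str, float] | float] = None,
            maxiter: int = 500) -> "MetaResults":
        """REML estimation with multi-start (boundary + method-of-moments)
        over the variance components, on the constrained scale."""
        G = len(self.groupings)
        if fix_tau2 is not None:
            if np.isscalar(fix_tau2):
                tau2 = np.full(G, float(fix_tau2))
            else:
                tau2 = np.array([float(fix_tau2[g]) for g in self.groupings])
            return self._results(tau2, converged=True)
        if G == 0:
            return self._results(np.zeros(0), converged=True)

        starts = [np.full(G, 1e-3), np.full(G, max(self._mom_start() / G, 1e-3))]
        best = None
        for x0 in starts:
            res = scipy.optimize.minimize(
                lambda t: self.reml_criterion(t), x0, method="L-BFGS-B",
                bounds=[(0.0, None)] * G,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise NotConvergedError(f"REML optimisation failed: {best.message}")
        tau2 = np.where(best.x < 1e-10, 0.0, best.x)
        return self._results(tau2, converged=bool(best.success))

    def _results(self, tau2: np.ndarray, converged: bool) -> "MetaResults":
        V = np.diag(self.s2).astype(float)
        for t, M in zip(tau2, self._ZZt):
            V += t * M
        Vi_X = np.linalg.solve(V, self.X)
        XtViX = self.X.T @ Vi_X
        cov = np.linalg.inv(XtViX)
        beta = cov @ (Vi_X.T @ self.y)
        return MetaResults(self, beta, cov, dict(zip(self.groupings, tau2)),
                           converged)


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pi_low: float
    pi_high: float


class MetaResults:
    """REML fit: pooled estimates per level, variance components, QM test
    and 95% prediction intervals."""

    method = "REML"

    def __init__(self, model: MultilevelMeta, beta: np.ndarray, cov: np.ndarray,
                 tau2: Mapping[str, float], converged: bool):
        self.model = model
        self.beta = beta
        self.cov = cov
        self.variance_components = dict(tau2)
        self.converged = converged
        self.total_tau2 = float(sum(tau2.values()))
        self.pooled: dict[str, PooledEstimate] = {}
        if model.moderator is None:
            self.pooled["overall"] = self._pooled_from_contrast(np.array([1.0]))
        else:
            for i, lv in enumerate(model.levels):
                c = self._level_contrast(i)
                self.pooled[lv] = self._pooled_from_contrast(c)

    def _level_contrast(self, i: int) -> np.ndarray:
        k = len(self.beta)
        c = np.zeros(k)
        if self.model.coding == "cell_means":
            c[i] = 1.0
        else:
            c[0] = 1.0
            if i > 0:
                c[i] = 1.0
        return c

    def _pooled_from_contrast(self, c: np.ndarray) -> PooledEstimate:
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov @ c))
        pi_se = float(np.sqrt(se ** 2 + self.total_tau2))
        return PooledEstimate(est, se, est - _Z95 * se, est + _Z95 * se,
                              est - _Z95 * pi_se, est + _Z95 * pi_se)

    @property
    def prediction_interval(self) -> dict[str, Tuple[float, float]]:
        return {k: (p.pi_low, p.pi_high) for k, p in self.pooled.items()}

    def moderator_test(self) -> Tuple[float, int, float]:
        """Omnibus Wald chi-square (QM) on the moderator coefficients.

        Reference coding tests the levels-1 deviations from the first
        level (df = levels-1); cell-means coding tests all level means
        jointly (df = levels).
        """
        if self.model.moderator is None:
            raise ModelInputError("fit has no moderator; QM test undefined")
        if self.model.coding == "cell_means":
            idx = np.arange(len(self.beta))
        else:
            idx = np.arange(1, len(self.beta))
        b = self.beta[idx]
        C = self.cov[np.ix_(idx, idx)]
        qm = float(b @ np.linalg.solve(C, b))
        df = len(idx)
        p = float(scipy.stats.chi2.sf(qm, df))
        return qm, df, p

    @property
    def qm(self) -> Optional[float]:
        return self.moderator_test()[0] if self.model.moderator else None

    def summary(self) -> str:
        lines = [f"Multilevel meta-analysis ({self.method}), "
                 f"n={len(self.model.y)} effects"]
        for lv, p in self.pooled.items():
            lines.append(f"  {lv:>16}: {p.estimate:8.4f} "
                         f"[{p.ci_low:.4f}, {p.ci_high:.4f}]  "
                         f"PI [{p.pi_low:.4f}, {p.pi_high:.4f}]")
        for g, t in self.variance_components.items():
            lines.append(f"  tau^2[{g}] = {t:.5f}")
        if self.model.moderator is not None:
            qm, df, p = self.moderator_test()
            lines.append(f"  QM = {qm:.2f}, df = {df}, p = {p:.4g}")
        return "\n".join(lines)

    def plot_forest(self, effects: Optional[pd.DataFrame] = None, ax=None):
        """Forest plot: pooled estimates with CIs, optionally the
        individual effects sized by precision (1/SE)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 2 + 0.4 * len(self.pooled)))
        if effects is not None and "effect" not in effects.columns:
            effects = effects.rename(columns={"coefficient": "effect"})
        labels = list(self.pooled)
        for i, lv in enumerate(labels):
            p = self.pooled[lv]
            ax.errorbar(p.estimate, i, xerr=[[p.estimate - p.ci_low],
                                             [p.ci_high - p.estimate]],
                        fmt="o", color="black", capsize=3)
            if effects is not None and self.model.moderator is not None:
                sub = effects[effects[self.model.moderator].astype(str) == lv]
                if len(sub):
                    ax.scatter(sub["effect"], np.full(len(sub), i) + 0.15,
                               s=20.0 / sub["se"], color="grey", alpha=0.5)
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(range(len(labels)), labels)
        ax.set_xlabel("standardized mixture effect (response-SD units)")
        return ax

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "pooled": {lv: {"estimate": p.estimate, "se": p.se,
                            "ci_low": p.ci_low, "ci_high": p.ci_high}
                       for lv, p in self.pooled.items()},
            "variance_components": self.variance_components,
            "prediction_interval": {k: list(v) for k, v in
                                    self.prediction_interval.items()},
        }
        if self.model.moderator is not None:
            qm, df, p = self.moderator_test()
            out.update({"qm": qm, "qm_df": df, "qm_p": p})
        return out


def fit_multilevel_meta(table: pd.DataFrame,
                        groupings: Sequence[str] = ("year", "country", "crop"),
                        moderator: Optional[str] = None,
                        coding: str = "reference", **fit_kws) -> MetaResults:
    """Fit the crossed-random-intercepts meta-analytic model by REML."""
    return MultilevelMeta(table, groupings, moderator, coding=coding).fit(**fit_kws)


def moderator_test(fit: MetaResults) -> Tuple[float, int, float]:
    """QM Wald chi-square on the moderator coefficients of ``fit``."""
    return fit.moderator_test()


def category_join(effects: pd.DataFrame,
                  classifications: Sequence[PairClassification]
                  ) -> Tuple[pd.DataFrame, list[str]]:
    """Attach each field pair's lab interaction category by unordered pair
    identity. Unmatched pairs are excluded and returned for reporting."""
    lookup = {}
    for c in classifications:
        lookup[frozenset(c.pair)] = c.category
    cats, keep = [], []
    excluded: list[str] = []
    for _, row in effects.iterrows():
        key = frozenset(str(row["pair"]).split("+"))
        if key in lookup:
            cats.append(lookup[key])
            keep.append(True)
        else:
            keep.append(False)
            excluded.append(str(row["pair"]))
    if excluded:
        warnings.warn(f"pairs without lab classification excluded: {sorted(set(excluded))}",
                      UserWarning, stacklevel=2)
    out = effects.loc[keep].copy()
    out["category"] = cats
    return out.reset_index(drop=True), sorted(set(excluded))


def forest_data(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-effect rows with precision weights (1/SE) for forest plotting."""
    out = effects.copy()
    out["weight"] = 1.0 / out["se"]
    return out
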