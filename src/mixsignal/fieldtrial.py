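"""Field-trial analysis: expected-mixture baselines and mixture effects.

A mixture plot's counterfactual "expected mixture" value is derived from
the design itself: on a Latin square it is the mean of the four monoculture
plots of the mixture's two component cultivars that share the plot's row
and column; on an RCBD it is the mean of the two component monoculture
plots in the same block. Observed mixture values are then compared to these
expected values with a linear mixed model (row + column, or block, and
sampling date as random intercepts; counts log(x+1)-transformed), and the
observed-vs-expected contrast for each pair is extracted as a standardized
coefficient with a Wald 95% CI — the effect size unit of the downstream
meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.formula.api as smf

from .errors import (IncompleteDesignError, InvalidIntervalError,
                     ModelInputError, StandardizationError)
from .simulate import (COUNT_VARIABLES, Treatment, TrialLayout, as_treatment,
                       treatment_label)

_Z95 = 1.96  # normal quantile used for all 95% Wald intervals
#: A variance component below this fraction of the residual variance marks
#: the mixed fit as singular and triggers the fixed-effects fallback.
_SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class ExpectedMixtureValue:
    """Design-derived counterfactual value for one mixture plot (and date)."""

    mixture_plot: str
    pair: Treatment
    date: Optional[str]
    value: float
    source_plots: Tuple[str, ...]


@dataclass(frozen=True)
class MixtureEffect:
    """Standardized observed-vs-expected coefficient for one trial, pair
    and variable; the unit of analysis of the meta-analysis."""

    trial: Tuple[str, str, str]  # (country, year, crop)
    pair: str
    variable: str
    coefficient: float
    ci_low: float
    ci_high: float
    se: float
    model_kind: str  # "mixed" | "fixed_fallback"
    n_obs: int


def effect_size_se(ci_low: float, ci_high: float) -> float:
    """Standard error recovered from a 95% CI as (upper - lower)/3.92."""
    if ci_high < ci_low:
        raise InvalidIntervalError(f"CI bounds out of order: ({ci_low}, {ci_high})")
    return (ci_high - ci_low) / 3.92


# ---------------------------------------------------------------------------
# aggregation and peak-window selection


def aggregate_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Sum aphid species per transect-date and natural-enemy taxa per
    plot-date; leave every other variable untouched."""
    if raw.empty:
        return raw.copy()
    parts = []
    aphids = raw[raw["variable"] == "aphids"]
    if len(aphids):
        g = (aphids.groupby(["plot_id", "date", "transect"], sort=False)["value"]
             .sum().reset_index())
        g["variable"], g["taxon"] = "aphids", ""
        parts.append(g)
    enemies = raw[raw["variable"] == "natural_enemies"]
    if len(enemies):
        g = (enemies.groupby(["plot_id", "date"], sort=False)["value"]
             .sum().reset_index())
        g["variable"], g["taxon"], g["transect"] = "natural_enemies", "", ""
        parts.append(g)
    other = raw[~raw["variable"].isin(["aphids", "natural_enemies"])]
    if len(other):
        parts.append(other.copy())
    out = pd.concat(parts, ignore_index=True)
    cols = ["plot_id", "date", "variable", "taxon", "transect", "value"]
    for c in cols:
        if c not in out.columns:
            out[c] = ""
    return out[cols]


def select_peak_window(data: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Keep the k consecutive sampling dates around the trial-wide aphid
    peak (the window containing the peak date with the largest total;
    earliest window on ties). The same window is applied to natural-enemy
    records; undated variables are untouched."""
    aphids = data[data["variable"] == "aphids"]
    dates = sorted(d for d in aphids["date"].unique() if d != "")
    if len(dates) <= k:
        return data.copy()
    totals = aphids.groupby("date")["value"].sum().reindex(dates).to_numpy()
    peak = int(np.argmax(totals))
    best, best_total = None, -np.inf
    for start in range(len(dates) - k + 1):
        if not start <= peak <= start + k - 1:
            continue
        tot = totals[start:start + k].sum()
        if tot > best_total:
            best, best_total = start, tot
    keep = set(dates[best:best + k])
    dated = data["variable"].isin(["aphids", "natural_enemies"])
    return data[~dated | data["date"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# expected mixture


def _plot_values(data: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Plot(-date) values of one variable: transect records averaged to the
    plot-date grain."""
    sub = data[data["variable"] == variable]
    keys = ["plot_id", "date"] if variable in ("aphids", "natural_enemies") else ["plot_id"]
    g = sub.groupby(keys, sort=False)["value"].mean().reset_index()
    if "date" not in g.columns:
        g["date"] = ""
    return g


def _mixture_and_mono_plots(layout: TrialLayout, pair: Treatment):
    treatments = layout.iter_plot_treatments()
    mix_plots = [p for p, t in treatments.items() if t == pair]
    mono = {c: [p for p, t in treatments.items() if t == (c,)] for c in pair}
    return treatments, mix_plots, mono


def expected_mixture(layout: TrialLayout, data: pd.DataFrame, pair: Treatment,
                     variable: str = "aphids") -> list[ExpectedMixtureValue]:
    """Expected-mixture values for every mixture plot of ``pair``.

    Latin square: mean of the 4 component-monoculture plots sharing the
    mixture plot's row and column. RCBD: mean of the 2 component-monoculture
    plots in the same block. Computed separately per sampling date.
    """
    pair = as_treatment(*pair)
    if len(pair) != 2:
        raise IncompleteDesignError(f"{pair!r} is not a two-cultivar mixture")
    treatments, mix_plots, mono = _mixture_and_mono_plots(layout, pair)
    if not mix_plots:
        raise IncompleteDesignError(f"layout has no mixture plot for {treatment_label(pair)}")
    plots = layout.plots.set_index("plot_id")
    values = _plot_values(data, variable).set_index(["plot_id", "date"])["value"]

    out = []
    for mp in mix_plots:
        sources = []
        missing = []
        if layout.design_kind == "latin_square":
            row, col = plots.loc[mp, "row"], plots.loc[mp, "col"]
            for c in pair:
                for dim, val in (("row", row), ("col", col)):
                    hits = [p for p in mono[c] if plots.loc[p, dim] == val]
                    if len(hits) != 1:
                        missing.append(f"monoculture {c} in {dim} {val}")
                    sources.extend(hits)
            expected_n = 4
        else:
            block = plots.loc[mp, "block"]
            for c in pair:
                hits = [p for p in mono[c] if plots.loc[p, "block"] == block]
                if len(hits) != 1:
                    missing.append(f"monoculture {c} in block {block}")
                sources.extend(hits)
            expected_n = 2
        if missing or len(sources) != expected_n:
            raise IncompleteDesignError(
                f"mixture plot {mp} ({treatment_label(pair)}): missing source plots: "
                + "; ".join(missing))
        dates = sorted({d for p, d in values.index if p == mp}) or [""]
        for date in dates:
            try:
                vals = [values.loc[(p, date)] for p in sources]
            except KeyError as exc:
                raise IncompleteDesignError(
                    f"no {variable!r} value for source plot {exc.args[0]!r}") from None
            out.append(ExpectedMixtureValue(mp, pair, date or None,
                                            float(np.mean(vals)), tuple(sources)))
    return out


def expected_table(values: Sequence[ExpectedMixtureValue]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mixture_plot": v.mixture_plot, "pair": treatment_label(v.pair),
        "date": v.date or "", "value": v.value,
        "source_plots": ";".join(v.source_plots)} for v in values])


# ---------------------------------------------------------------------------
# observed-vs-expected mixed model


class _GLSFit:
    """Minimal GLS result container for the REML mixed fit."""

    def __init__(self, params: pd.Series, bse: pd.Series, fittedvalues: np.ndarray,
                 resid: np.ndarray, vcomp: dict, scale: float, converged: bool):
        self.params = params
        self.bse = bse
        self.fittedvalues = fittedvalues
        self.resid = resid
        self.vcomp = vcomp
        self.scale = scale
        self.converged = converged


class MixtureModel:
    """Linear (mixed) model of observed vs expected mixture values.

    The fixed part is pair + pair:observed (the per-pair observed-vs-
    expected contrast; the pair term is dropped for single-pair trials);
    row and column (or block), and sampling date where present, enter as
    crossed random intercepts estimated by REML. If any variance component
    hits the zero boundary the model is refitted with those grouping
    factors as fixed terms (``fixed_fallback``).
    """

    def __init__(self, frame: pd.DataFrame, design_kind: str, variable: str,
                 log_transform: Optional[bool] = None):
        if set(frame["vtype"]) != {"observed", "expected"}:
            raise ModelInputError("need both observed and expected value types")
        self.variable = variable
        self.design_kind = design_kind
        if log_transform is None:
            log_transform = variable in COUNT_VARIABLES
        self.log_transform = log_transform
        frame = frame.copy()
        frame["obs"] = (frame["vtype"] == "observed").astype(float)
        frame["y"] = np.log1p(frame["value"]) if log_transform else frame["value"]
        self.frame = frame.reset_index(drop=True)
        self.pairs = sorted(frame["pair"].unique())
        self.has_date = "date" in frame.columns and frame["date"].nunique() > 1
        if len(self.pairs) > 1:
            self.fixed_formula = "y ~ C(pair) + C(pair):obs"
        else:
            self.fixed_formula = "y ~ obs"
        self._check_rank()

    @classmethod
    def from_trial(cls, layout: TrialLayout, data: pd.DataFrame, variable: str,
                   pairs: Optional[Sequence[Treatment]] = None,
                   log_transform: Optional[bool] = None) -> "MixtureModel":
        """Build the observed+expected comparison frame for one trial."""
        if pairs is None:
            pairs = [t for t in layout.treatments() if len(t) == 2]
        plots = layout.plots.set_index("plot_id")
        obs_values = _plot_values(data, variable).set_index(["plot_id", "date"])["value"]
        rows = []
        for pair in pairs:
            pair = as_treatment(*pair)
            for ev in expected_mixture(layout, data, pair, variable):
                coords = plots.loc[ev.mixture_plot]
                common = {"pair": treatment_label(pair), "date": ev.date or "",
                          "row": coords["row"], "col": coords["col"],
                          "block": coords["block"], "plot_id": ev.mixture_plot}
                rows.append({**common, "vtype": "expected", "value": ev.value})
                rows.append({**common, "vtype": "observed",
                             "value": float(obs_values.loc[(ev.mixture_plot, ev.date or "")])})
        if not rows:
            raise ModelInputError(f"no observed/expected rows for variable {variable!r}")
        return cls(pd.DataFrame(rows), layout.design_kind, variable,
                   log_transform=log_transform)

    def _grouping_columns(self) -> list[str]:
        cols = (["row", "col"] if self.design_kind == "latin_square" else ["block"])
        if self.has_date:
            cols.append("date")
        return cols

    def _fallback_formula(self) -> str:
        extra = (["C(row)", "C(col)"] if self.design_kind == "latin_square"
                 else ["C(block)"])
        if self.has_date:
            extra.append("C(date)")
        return self.fixed_formula + " + " + " + ".join(extra)

    def _check_rank(self):
        import patsy
        _, X = patsy.dmatrices(self.fixed_formula, self.frame, return_type="dataframe")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            _, _, piv = scipy.linalg.qr(X.to_numpy(), pivoting=True)
            aliased = [X.columns[i] for i in piv[rank:]]
            raise ModelInputError(f"rank-deficient fixed effects; aliased terms: {aliased}")

    def _reml_fit(self) -> _GLSFit:
        """REML over residual + grouping variance components; the response
        is rescaled to unit SD internally for optimizer conditioning."""
        import patsy
        from .meta import _reml_neg2

        yd, Xd = patsy.dmatrices(self.fixed_formula, self.frame,
                                 return_type="dataframe")
        y = yd.to_numpy().ravel()
        X = Xd.to_numpy()
        n = len(y)
        s = float(np.std(y, ddof=1))
        s = s if s > 0 else 1.0
        ys = y / s
        groups = self._grouping_columns()
        ZZt = [np.eye(n)]
        for g in groups:
            codes, _ = pd.factorize(self.frame[g])
            Z = np.eye(codes.max() + 1)[codes]
            ZZt.append(Z @ Z.T)
        zeros = np.zeros(n)

        def crit(t):
            return _reml_neg2(ys, X, zeros, ZZt, t)

        k = len(ZZt)
        starts = [np.r_[1.0, np.full(k - 1, 0.05)],
                  np.r_[0.5, np.full(k - 1, 0.3)]]
        bounds = [(1e-8, None)] + [(0.0, None)] * (k - 1)
        best = None
        for x0 in starts:
            for method in ("L-BFGS-B", "Powell"):
                try:
                    r = scipy.optimize.minimize(
                        crit, x0, method=method, bounds=bounds,
                        options={"maxiter": 500} if method == "Powell" else
                        {"ftol": 1e-13, "gtol": 1e-11, "maxiter": 500})
                except ValueError:  # line search stepping outside bounds
                    continue
                if np.isfinite(r.fun) and (best is None or r.fun < best.fun):
                    best = r
                break
        if best is None:
            r = scipy.optimize.minimize(crit, starts[0], method="Powell",
                                        bounds=bounds, options={"maxiter": 1000})
            best = r
        tau = best.x * s ** 2  # back to the response scale
        V = tau[0] * np.eye(n)
        for t, M in zip(tau[1:], ZZt[1:]):
            V += t * M
        Vi_X = np.linalg.solve(V, X)
        cov = np.linalg.inv(X.T @ Vi_X)
        beta = cov @ (Vi_X.T @ y)
        names = list(Xd.columns)
        fitted = X @ beta
        return _GLSFit(pd.Series(beta, index=names),
                       pd.Series(np.sqrt(np.diag(cov)), index=names),
                       fitted, y - fitted,
                       dict(zip(groups, tau[1:])), float(tau[0]),
                       converged=bool(best.success and np.isfinite(best.fun)))

    def fit(self) -> "MixtureResults":
        res = self._reml_fit()
        singular = (not res.converged
                    or any(v < _SINGULAR_TOL * res.scale for v in res.vcomp.values()))
        if singular:
            ols = smf.ols(self._fallback_formula(), self.frame).fit()
            return MixtureResults(self, ols, model_kind="fixed_fallback")
        return MixtureResults(self, res, model_kind="mixed")


class MixtureResults:
    """Fitted observed-vs-expected comparison for one trial and variable."""

    def __init__(self, model: MixtureModel, res, model_kind: str):
        self.model = model
        self._res = res
        self.model_kind = model_kind
        self.n_obs = len(model.frame)
        self.converged = bool(getattr(res, "converged", True))
        if model_kind == "mixed":
            self.variance_components = dict(res.vcomp)
            self.residual_variance = float(res.scale)
        else:
            self.variance_components = {}
            self.residual_variance = float(res.mse_resid)

    def _param_name(self, pair: str) -> str:
        if pair not in self.model.pairs:
            raise ModelInputError(f"pair {pair!r} is not in the model "
                                  f"(pairs: {self.model.pairs})")
        names = list(self._res.params.index)
        if len(self.model.pairs) == 1:
            return "obs"
        for name in names:
            if name.endswith(":obs") and f"[{pair}]" in name:
                return name
        raise ModelInputError(f"no observed-vs-expected coefficient for pair {pair!r}")

    def coefficient(self, pair: str) -> tuple[float, float]:
        """Raw observed-vs-expected coefficient and SE for one pair."""
        name = self._param_name(pair)
        return float(self._res.params[name]), float(self._res.bse[name])

    @property
    def df_resid(self) -> float:
        """Containment-style denominator df: observations minus fixed-effect
        rank minus the random-intercept levels spent."""
        if self.model_kind == "fixed_fallback":
            return float(self._res.df_resid)
        p = len(self._res.params)
        q = sum(self.model.frame[g].nunique() - 1
                for g in self.model._grouping_columns())
        return float(max(self.n_obs - p - q, 3))

    def coefficient_ci(self, pair: str) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) at 95%, using a t quantile on the
        containment df (the OLS residual df for the fixed fallback)."""
        name = self._param_name(pair)
        est = float(self._res.params[name])
        if self.model_kind == "mixed":
            se = float(self._res.bse[name])
            tq = float(scipy.stats.t.ppf(0.975, self.df_resid))
            return est, est - tq * se, est + tq * se
        ci = self._res.conf_int().loc[name]
        return est, float(ci[0]), float(ci[1])

    def standardized_coefficient(self, pair: str,
                                 trial: Tuple[str, str, str] = ("", "", "")) -> MixtureEffect:
        """Observed-vs-expected contrast in response-SD units with its
        95% CI, from a refit on the standardized response."""
        sd = float(self.model.frame["y"].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise StandardizationError(
                f"response for {self.model.variable!r} has zero variance")
        frame = self.model.frame.copy()
        frame["value"] = (frame["y"] - frame["y"].mean()) / sd
        cols = [c for c in ("pair", "vtype", "value", "date", "row", "col",
                            "block", "plot_id") if c in frame.columns]
        std_model = MixtureModel(frame[cols], self.model.design_kind,
                                 self.model.variable, log_transform=False)
        # keep the raw fit's model kind: the standardized refit only
        # rescales, it must not flip between mixed and fallback
        if self.model_kind == "mixed":
            std_res = MixtureResults(std_model, std_model._reml_fit(), "mixed")
        else:
            ols = smf.ols(std_model._fallback_formula(), std_model.frame).fit()
            std_res = MixtureResults(std_model, ols, model_kind="fixed_fallback")
        est, lo, hi = std_res.coefficient_ci(pair)
        return MixtureEffect(trial, pair, self.model.variable, est, lo, hi,
                             effect_size_se(lo, hi), self.model_kind, self.n_obs)

    def diagnostics(self) -> dict:
        """Simple residual checks: normal-quantile correlation and the
        fitted-vs-|residual| (scale-location) correlation. Out-of-range
        values warn, never abort."""
        resid = np.asarray(self._res.resid if self.model_kind == "fixed_fallback"
                           else self.model.frame["y"] - self._res.fittedvalues)
        fitted = np.asarray(self._res.fittedvalues)
        qq = scipy.stats.probplot(resid, dist="norm")
        qq_corr = float(np.corrcoef(qq[0][0], qq[0][1])[0, 1])
        if np.std(fitted) > 0 and np.std(np.abs(resid)) > 0:
            sl = float(np.corrcoef(fitted, np.abs(resid))[0, 1])
        else:
            sl = 0.0
        out = {"qq_correlation": qq_corr, "scale_location_correlation": sl}
        if qq_corr < 0.9:
            warnings.warn(f"residual normal-quantile correlation low ({qq_corr:.3f}) "
                          f"for {self.model.variable}", UserWarning, stacklevel=2)
        return out

    def summary(self) -> str:
        lines = [f"Observed-vs-expected model: {self.model.variable} "
                 f"({self.model_kind}, n={self.n_obs}, "
                 f"log1p={self.model.log_transform})"]
        for p in self.model.pairs:
            est, se = self.coefficient(p)
            lines.append(f"  {p:>20}: obs-exp = {est:8.4f} ({se:.4f})")
        for k, v in self.variance_components.items():
            lines.append(f"  var[{k}] = {v:.4f}")
        lines.append(f"  residual var = {self.residual_variance:.4f}")
        return "\n".join(lines)


def fit_mixture_model(frame: pd.DataFrame, design_kind: str, variable: str,
                      **kws) -> MixtureResults:
    """Fit the observed-vs-expected comparison on a prepared frame with
    columns pair, vtype, value, row/col or block, optional date."""
    return MixtureModel(frame, design_kind, variable, **kws).fit()


def analyze_trial(layout: TrialLayout, data: pd.DataFrame,
                  variables: Sequence[str] = ("aphids",),
                  trial: Tuple[str, str, str] = ("", "", ""),
                  peak_window: int = 3,
                  aggregate: bool = True,
                  per_pair: bool = False) -> tuple[list[MixtureEffect], list[MixtureResults]]:
    """One trial end to end: aggregate counts, select the peak window,
    build expected mixtures, fit per-variable models and extract one
    standardized effect per pair.

    ``per_pair=True`` refits a separate model for each pair instead of one
    joint model with pair-within-type contrasts; the per-pair route keeps
    each pair's expected rows independent of the other pairs' source plots.
    """
    if aggregate:
        data = aggregate_counts(data)
    data = select_peak_window(data, k=peak_window)
    all_pairs = [t for t in layout.treatments() if len(t) == 2]
    effects, fits = [], []
    for var in variables:
        pair_sets = [[p] for p in all_pairs] if per_pair else [None]
        for pairs in pair_sets:
            res = MixtureModel.from_trial(layout, data, var, pairs=pairs).fit()
            fits.append(res)
            for pair in res.model.pairs:
                effects.append(res.standardized_coefficient(pair, trial=trial))
    return effects, fits


def effects_table(effects: Sequence[MixtureEffect]) -> pd.DataFrame:
    return pd.DataFrame([{
        "country": e.trial[0], "year": e.trial[1], "crop": e.trial[2],
        "pair": e.pair, "variable": e.variable, "coefficient": e.coefficient,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "se": e.se,
        "model_kind": e.model_kind, "n_obs": e.n_obs} for e in effects])
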