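"""Laboratory screening of cultivar pairs from aphid-settling bioassays.

Tube-level settling counts are analyzed with a binomial generalized linear
mixed model on the logit scale: one fixed cell mean per (emitter, receiver)
combination — equivalent to emitter + receiver + interaction — and a
pot-level Gaussian random intercept. The marginal likelihood integrates the
pot intercept out with Gauss-Hermite quadrature, which is exact in the
single-scalar-random-effect limit as the node count grows. Each exposed
cell is contrasted against its receiver's clean-air control on the logit
scale; a cultivar pair is then classified as showing no, one-way or two-way
volatile interaction according to which directions show a significant
reduction in settling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import gammaln, logsumexp
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

from .errors import (InvalidPairError, MissingCellError, ModelInputError,
                     NotConvergedError)
from .simulate import CONTROL

Cell = Tuple[str, str]  # (emitter, receiver)

#: Pot variance estimated below this (on the SD scale) is reported as a
#: boundary estimate of exactly zero and the model is refitted as a plain
#: logistic regression.
_SD_BOUNDARY = 1e-4


@dataclass(frozen=True)
class DirectionalTest:
    """One emitter-vs-control contrast for a receiver cultivar."""

    emitter: str
    receiver: str
    contrast: float  # receiver-under-emitter minus receiver-under-control
    se: float
    p_unadjusted: float
    p_bonferroni: float
    significant_reduction: bool

    @property
    def pair(self) -> Tuple[str, str]:
        return tuple(sorted((self.emitter, self.receiver)))


@dataclass(frozen=True)
class PairClassification:
    """Lab interaction category of an unordered cultivar pair."""

    cultivar_a: str
    cultivar_b: str
    test_ab: DirectionalTest
    test_ba: DirectionalTest
    category: str  # no_interaction | one_way | two_way
    one_way_direction: Optional[Cell] = None

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.cultivar_a, self.cultivar_b)


class AcceptanceModel:
    """Binomial GLMM for tube-level aphid plant acceptance.

    Parameters
    ----------
    data : DataFrame
        Columns receiver, emitter, pot_id, settled, placed; ``emitter`` is a
        cultivar name or the clean-air sentinel ``"CONTROL"``.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"receiver", "emitter", "pot_id", "settled", "placed"}
        missing = required - set(data.columns)
        if missing:
            raise ModelInputError(f"bioassay data lacks columns {sorted(missing)}")
        if ((data["settled"] < 0) | (data["settled"] > data["placed"])).any():
            raise ModelInputError("settled counts must lie in [0, placed]")
        if data["receiver"].nunique() < 2 and data["emitter"].nunique() < 2:
            raise ModelInputError("need at least 2 receiver or 2 emitter levels")
        self.data = data.reset_index(drop=True)

        cells = sorted(set(zip(self.data["emitter"], self.data["receiver"])))
        self.cells: list[Cell] = cells
        cell_idx = {c: i for i, c in enumerate(cells)}
        # pots are nested within cells; collapse tubes to per-pot binomial
        # sufficient statistics (all tubes in a pot share one logit)
        grp = self.data.groupby(["emitter", "receiver", "pot_id"], sort=True)
        agg = grp.agg(S=("settled", "sum"), N=("placed", "sum")).reset_index()
        self._pot_cell = np.array([cell_idx[(e, r)] for e, r in
                                   zip(agg["emitter"], agg["receiver"])])
        self._S = agg["S"].to_numpy(dtype=float)
        self._N = agg["N"].to_numpy(dtype=float)
        self._const = float(np.sum(gammaln(self.data["placed"] + 1)
                                   - gammaln(self.data["settled"] + 1)
                                   - gammaln(self.data["placed"] - self.data["settled"] + 1)))
        self.separated_cells = self._find_separated()

    def _find_separated(self) -> set[Cell]:
        out = set()
        g = self.data.groupby(["emitter", "receiver"])
        for (e, r), sub in g:
            tot_s, tot_n = sub["settled"].sum(), sub["placed"].sum()
            if tot_s == 0 or tot_s == tot_n:
                out.add((e, r))
        return out

    # -- marginal log likelihood -------------------------------------------

    def loglike(self, beta: np.ndarray, sigma: float, n_quad: int = 31) -> float:
        """Marginal binomial log likelihood with the pot intercept
        integrated out by Gauss-Hermite quadrature."""
        if sigma < _SD_BOUNDARY:
            eta = beta[self._pot_cell]
            ll = self._S * eta - self._N * np.logaddexp(0.0, eta)
            return float(ll.sum() + self._const)
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        log_w = np.log(weights) - 0.5 * np.log(2 * np.pi)
        eta = beta[self._pot_cell][:, None] + sigma * nodes[None, :]
        ll_nodes = self._S[:, None] * eta - self._N[:, None] * np.logaddexp(0.0, eta)
        return float(logsumexp(log_w[None, :] + ll_nodes, axis=1).sum() + self._const)

    def fit(self, n_quad: int = 31, maxiter: int = 500) -> "AcceptanceResults":
        """Maximize the marginal likelihood over cell means and pot SD."""
        if self.separated_cells:
            warnings.warn(
                "complete separation in cells "
                f"{sorted(self.separated_cells)}; they are excluded from contrasts",
                UserWarning, stacklevel=2)
        k = len(self.cells)
        # empirical-logit starting values per cell
        g = self.data.groupby(["emitter", "receiver"])
        beta0 = np.zeros(k)
        for i, c in enumerate(self.cells):
            sub = g.get_group(c)
            p = (sub["settled"].sum() + 0.5) / (sub["placed"].sum() + 1.0)
            beta0[i] = np.log(p / (1 - p))
        x0 = np.concatenate([beta0, [0.2]])
        bounds = [(-25.0, 25.0)] * k + [(0.0, 10.0)]

        def nll(x):
            return -self.loglike(x[:k], x[k], n_quad=n_quad)

        res = scipy.optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                      options={"maxiter": maxiter, "ftol": 1e-12,
                                               "gtol": 1e-8})
        converged = bool(res.success)
        beta, sigma = res.x[:k], float(res.x[k])

        if sigma < _SD_BOUNDARY:
            return self._fit_logistic(converged)

        hess = approx_hess1(res.x, nll)
        try:
            cov_full = np.linalg.inv(hess)
            cov = cov_full[:k, :k]
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            converged = False
            cov = np.full((k, k), np.nan)
        return AcceptanceResults(self, beta, cov, pot_variance=sigma ** 2,
                                 converged=converged, method="glmm_agq",
                                 loglike=-res.fun)

    def _fit_logistic(self, converged: bool) -> "AcceptanceResults":
        """Boundary refit: pot variance 0 -> ordinary logistic regression
        with the same cell-mean design."""
        k = len(self.cells)
        idx = pd.Categorical(list(zip(self.data["emitter"], self.data["receiver"])),
                             categories=self.cells).codes
        exog = np.eye(k)[idx]
        endog = np.column_stack([self.data["settled"],
                                 self.data["placed"] - self.data["settled"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perfect-separation cells diverge
            glm = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
        return AcceptanceResults(self, np.asarray(glm.params),
                                 np.asarray(glm.cov_params()), pot_variance=0.0,
                                 converged=converged, method="logistic_boundary",
                                 loglike=float(glm.llf))


class AcceptanceResults:
    """Fitted acceptance model: cell means on the logit scale, their
    covariance, and the pot variance component."""

    def __init__(self, model: AcceptanceModel, beta: np.ndarray, cov: np.ndarray,
                 pot_variance: float, converged: bool, method: str, loglike: float):
        self.model = model
        self._beta = beta
        self._cov = cov
        self.pot_variance = float(pot_variance)
        self.converged = converged
        self.method = method
        self.loglike = loglike
        self.cell_means: Mapping[Cell, float] = {
            c: float(beta[i]) for i, c in enumerate(model.cells)}
        self.fixed_effects: Mapping[Cell, Tuple[float, float]] = {
            c: (float(beta[i]), float(np.sqrt(cov[i, i])))
            for i, c in enumerate(model.cells)}

    def _cell_index(self, emitter: str, receiver: str) -> int:
        try:
            return self.model.cells.index((emitter, receiver))
        except ValueError:
            raise MissingCellError(f"cell (emitter={emitter!r}, receiver={receiver!r}) "
                                   "is not in the fitted model") from None

    def compare_to_control(self, emitter: str, receiver: str,
                           family_size: int = 1, alpha: float = 0.05,
                           adjust: str = "none") -> DirectionalTest:
        """Contrast a receiver's settling under an emitter against its
        clean-air control (logit scale, large-sample two-sided Wald test)."""
        if not self.converged:
            raise NotConvergedError("refusing contrasts from a non-converged fit")
        for cell in ((emitter, receiver), (CONTROL, receiver)):
            if cell in self.model.separated_cells:
                warnings.warn(f"cell {cell} excluded from contrasts: complete separation",
                              UserWarning, stacklevel=2)
                raise MissingCellError(f"cell {cell} excluded: complete separation")
        i = self._cell_index(emitter, receiver)
        j = self._cell_index(CONTROL, receiver)
        contrast = self._beta[i] - self._beta[j]
        var = self._cov[i, i] + self._cov[j, j] - 2 * self._cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            p = 1.0 if contrast == 0 else 0.0
        else:
            p = float(2 * scipy.stats.norm.sf(abs(contrast) / se))
        p_bonf = min(1.0, family_size * p)
        p_used = p_bonf if adjust == "bonferroni" else p
        return DirectionalTest(emitter, receiver, float(contrast), se, p, p_bonf,
                               significant_reduction=bool(contrast < 0 and p_used < alpha))

    def summary(self) -> str:
        lines = [f"Binomial mixed model of aphid plant acceptance ({self.method})",
                 f"  pot variance: {self.pot_variance:.4f}   converged: {self.converged}",
                 f"  log-likelihood: {self.loglike:.2f}",
                 "  cell means (logit scale):"]
        for c, (est, se) in self.fixed_effects.items():
            lines.append(f"    {c[0]:>14} -> {c[1]:<14} {est:8.3f} ({se:.3f})")
        return "\n".join(lines)


def fit_acceptance_model(data: pd.DataFrame, **fit_kws) -> AcceptanceResults:
    """Fit the tube-level binomial GLMM (cell means + pot random intercept)."""
    return AcceptanceModel(data).fit(**fit_kws)


def compare_to_control(fit: AcceptanceResults, emitter: str, receiver: str,
                       family_size: int = 1, **kws) -> DirectionalTest:
    return fit.compare_to_control(emitter, receiver, family_size=family_size, **kws)


def classify_pair(test_ab: DirectionalTest, test_ba: DirectionalTest) -> PairClassification:
    """Combine the two directions of a cultivar pair into an interaction
    category: two_way if both show significant reductions, one_way if
    exactly one does, no_interaction otherwise."""
    if test_ab.pair != test_ba.pair or test_ab.emitter != test_ba.receiver:
        raise InvalidPairError(
            f"tests ({test_ab.emitter}->{test_ab.receiver}) and "
            f"({test_ba.emitter}->{test_ba.receiver}) do not describe opposite "
            "directions of one pair")
    a, b = test_ab.pair
    sig = (test_ab.significant_reduction, test_ba.significant_reduction)
    if all(sig):
        cat, direction = "two_way", None
    elif any(sig):
        winner = test_ab if sig[0] else test_ba
        cat, direction = "one_way", (winner.emitter, winner.receiver)
    else:
        cat, direction = "no_interaction", None
    return PairClassification(a, b, test_ab, test_ba, cat, direction)


def directional_test_from_summary(emitter: str, receiver: str,
                                  mean_exposed: float, mean_control: float,
                                  p_value: float, alpha: float = 0.05,
                                  family_size: int = 1) -> DirectionalTest:
    """Build a directional test from published summary statistics (group
    means and a p-value) instead of a fitted model. The contrast is the
    reported-scale mean difference; only its sign enters classification."""
    contrast = float(mean_exposed - mean_control)
    p_bonf = min(1.0, family_size * p_value)
    return DirectionalTest(emitter, receiver, contrast, np.nan, float(p_value),
                           p_bonf, significant_reduction=bool(contrast < 0
                                                              and p_value < alpha))


def screen_bioassay(data: pd.DataFrame, alpha: float = 0.05, adjust: str = "none",
                    family_size: Optional[int] = None,
                    **fit_kws) -> tuple[list[PairClassification], pd.DataFrame]:
    """Full screening: fit the GLMM, run every emitter-vs-control contrast,
    classify every unordered pair with both directions available.

    Returns the classifications and a tidy table of directional tests.
    """
    fit = fit_acceptance_model(data, **fit_kws)
    exposed = [(e, r) for (e, r) in fit.model.cells if e != CONTROL]
    if family_size is None:
        family_size = len(exposed)
    tests: dict[Cell, DirectionalTest] = {}
    for (e, r) in exposed:
        try:
            tests[(e, r)] = fit.compare_to_control(e, r, family_size=family_size,
                                                   alpha=alpha, adjust=adjust)
        except MissingCellError:
            continue
    classifications = []
    for (e, r), t in sorted(tests.items()):
        if (r, e) in tests and e < r:
            classifications.append(classify_pair(t, tests[(r, e)]))
    rows = [{"emitter": t.emitter, "receiver": t.receiver, "contrast": t.contrast,
             "se": t.se, "p_unadjusted": t.p_unadjusted,
             "p_bonferroni": t.p_bonferroni,
             "significant_reduction": t.significant_reduction}
            for t in tests.values()]
    return classifications, pd.DataFrame(rows)


def classifications_table(classifications: list[PairClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append({
            "cultivar_a": c.cultivar_a, "cultivar_b": c.cultivar_b,
            "category": c.category,
            "one_way_emitter": c.one_way_direction[0] if c.one_way_direction else "",
            "one_way_receiver": c.one_way_direction[1] if c.one_way_direction else "",
            "p_ab": c.test_ab.p_unadjusted, "p_ba": c.test_ba.p_unadjusted,
        })
    return pd.DataFrame(rows)
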