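"""Synthetic bioassay and field-trial data with known ground truth.

The generators mirror the data-collection protocols the analysis stages
assume: tube-level aphid settling counts with pot-level random intercepts,
and field counts/traits on Latin-square or randomized-complete-block
layouts with row/column (or block), date and plot effects. Every generator
takes an explicit integer seed and returns tidy pandas tables, so each
downstream stage can be tested against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidScenarioError

#: Sentinel emitter level for receivers exposed to clean air.
CONTROL = "CONTROL"

#: A treatment is a sorted tuple of one (monoculture) or two (50:50 mixture)
#: cultivar names.
Treatment = Tuple[str, ...]

APHID_SPECIES = ("R_padi", "M_dirhodum", "S_avenae")
APHID_SPECIES_PROPS = (0.60, 0.25, 0.15)
ENEMY_TAXA = ("Coccinellidae", "Syrphidae")
ENEMY_TAXA_PROPS = (0.7, 0.3)

COUNT_VARIABLES = ("aphids", "natural_enemies")
TRAIT_VARIABLES = ("height", "plant_count", "tgw", "yield")


def as_treatment(*cultivars: str) -> Treatment:
    """Canonical (sorted, deduplicated) treatment tuple."""
    t = tuple(sorted(set(c for c in cultivars if c)))
    if not 1 <= len(t) <= 2:
        raise InvalidScenarioError(f"treatment must name 1 or 2 cultivars, got {cultivars!r}")
    return t


def treatment_label(treatment: Treatment) -> str:
    return "+".join(treatment)


@dataclass(frozen=True)
class TrialLayout:
    """Plot layout of one field trial.

    ``plots`` has columns plot_id, row, col, block, cultivar_1, cultivar_2
    (cultivar_2 empty for monocultures). Rows/columns/blocks are 1-based
    labels without arithmetic meaning.
    """

    design_kind: str  # "latin_square" | "rcbd"
    plots: pd.DataFrame

    def __post_init__(self):
        if self.design_kind not in ("latin_square", "rcbd"):
            raise InvalidScenarioError(f"unknown design kind {self.design_kind!r}")

    def treatments(self) -> list[Treatment]:
        seen: dict[Treatment, None] = {}
        for t in self.iter_plot_treatments().values():
            seen.setdefault(t, None)
        return list(seen)

    def iter_plot_treatments(self) -> dict[str, Treatment]:
        out = {}
        for rec in self.plots.itertuples(index=False):
            c2 = rec.cultivar_2
            if isinstance(c2, float):  # NaN from a round-tripped CSV
                c2 = ""
            out[rec.plot_id] = as_treatment(*(c for c in (rec.cultivar_1, c2) if c))
        return out


@dataclass
class BioassayScenario:
    """Ground truth for a tube-settling bioassay.

    ``effect_logit`` maps (emitter, receiver) to the shift in settling
    log-odds relative to the clean-air control for that receiver; negative
    values mean priming (reduced acceptance). The control level carries a
    zero shift by construction.
    """

    receivers: Sequence[str]
    emitters: Sequence[str] = ()
    baseline_logit: float = 1.5
    effect_logit: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    pot_sd: float = 0.3
    aphids_per_tube: int = 10
    tubes_per_combination: int = 20
    pots_per_treatment: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.emitters:
            self.emitters = tuple(self.receivers)
        if self.aphids_per_tube < 1:
            raise InvalidScenarioError("aphids_per_tube must be >= 1")
        if self.tubes_per_combination < 1:
            raise InvalidScenarioError("tubes_per_combination must be >= 1")
        if self.pots_per_treatment < 1:
            raise InvalidScenarioError("pots_per_treatment must be >= 1")
        if self.pot_sd < 0:
            raise InvalidScenarioError("pot_sd must be >= 0")
        for (em, rc) in self.effect_logit:
            if em == CONTROL:
                raise InvalidScenarioError("control level carries no effect shift")

    def cells(self) -> list[Tuple[str, str]]:
        """(emitter, receiver) cells generated: all ordered distinct pairs
        plus one clean-air control cell per receiver."""
        out = [(CONTROL, r) for r in self.receivers]
        out += [(e, r) for r in self.receivers for e in self.emitters if e != r]
        return out


@dataclass
class FieldScenario:
    """Ground truth for one field trial's measurements.

    Counts follow a log-linear negative-binomial law: the per-transect
    log-mean is log(plot mean) plus row + column (or block) + date + plot
    Gaussian effects; ``overdispersion`` is the gamma shape (None = pure
    Poisson). A mixture plot's mean is ``mixture_multiplier`` times the
    arithmetic mean of its components' monoculture means. Trait variables
    are drawn per plot with additive Gaussian structure on their own scale.
    """

    cultivars: Sequence[str]
    treatments: Sequence[Treatment] = ()
    cultivar_mean: Mapping[str, float] = field(default_factory=dict)  # aphids / transect
    mixture_multiplier: Mapping[Treatment, float] = field(default_factory=dict)
    dates: Sequence[str] = ("2021-06-01", "2021-06-08", "2021-06-15")
    row_sd: float = 0.15
    col_sd: float = 0.15
    block_sd: float = 0.15
    date_sd: float = 0.25
    plot_sd: float = 0.15
    overdispersion: Optional[float] = 4.0
    transects_per_plot: int = 3
    enemy_mean: float = 2.0
    enemy_multiplier: Mapping[Treatment, float] = field(default_factory=dict)
    trait_means: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    trait_multiplier: Mapping[str, Mapping[Treatment, float]] = field(default_factory=dict)
    trait_sd: Mapping[str, float] = field(default_factory=dict)
    trait_design_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    #: Realistic monoculture trait levels for a temperate cereal crop:
    #: height in cm at flag-leaf stage, plants per 1-m transect, thousand
    #: grain weight in g, yield in kg/ha.
    DEFAULT_TRAIT_MEANS = {"height": 80.0, "plant_count": 60.0, "tgw": 42.0, "yield": 6000.0}
    DEFAULT_TRAIT_SD = {"height": 4.0, "plant_count": 6.0, "tgw": 2.0, "yield": 400.0}

    def __post_init__(self):
        self.mixture_multiplier = {as_treatment(*k): v for k, v in self.mixture_multiplier.items()}
        self.enemy_multiplier = {as_treatment(*k): v for k, v in self.enemy_multiplier.items()}
        if not self.cultivar_mean:
            self.cultivar_mean = {c: 8.0 for c in self.cultivars}
        if not self.treatments:
            monos = [as_treatment(c) for c in self.cultivars]
            pairs = [as_treatment(a, b)
                     for i, a in enumerate(self.cultivars)
                     for b in list(self.cultivars)[i + 1:]]
            self.treatments = monos + pairs
        self.treatments = [as_treatment(*t) for t in self.treatments]
        for c, m in self.cultivar_mean.items():
            if m <= 0:
                raise InvalidScenarioError(f"cultivar mean for {c!r} must be > 0")
        for p, m in self.mixture_multiplier.items():
            if m <= 0:
                raise InvalidScenarioError(f"mixture multiplier for {p!r} must be > 0")
        for sd in (self.row_sd, self.col_sd, self.block_sd, self.date_sd, self.plot_sd):
            if sd < 0:
                raise InvalidScenarioError("variance components must be >= 0")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise InvalidScenarioError("overdispersion must be > 0 or None")
        if self.transects_per_plot < 1:
            raise InvalidScenarioError("transects_per_plot must be >= 1")

    def treatment_mean(self, treatment: Treatment, means: Mapping[str, float],
                       multipliers: Mapping[Treatment, float]) -> float:
        base = float(np.mean([means[c] for c in treatment]))
        if len(treatment) == 2:
            base *= multipliers.get(treatment, 1.0)
        return base


# ---------------------------------------------------------------------------
# layouts


def generate_latin_square(n_treatments: int, seed: int,
                          treatments: Optional[Sequence[Treatment]] = None) -> TrialLayout:
    """Uniformly randomized n x n Latin square layout.

    Randomization permutes the rows, columns and symbol labels of a cyclic
    base square, so each treatment occurs exactly once per row and column.
    """
    if n_treatments < 2:
        raise InvalidScenarioError("a Latin square needs at least 2 treatments")
    if treatments is None:
        treatments = [as_treatment(f"T{i + 1}") for i in range(n_treatments)]
    if len(treatments) != n_treatments:
        raise InvalidScenarioError("treatments list must match n_treatments")
    n = n_treatments
    rng = np.random.default_rng(seed)
    rperm, cperm, sperm = (rng.permutation(n) for _ in range(3))
    rows = []
    for i in range(n):
        for j in range(n):
            sym = sperm[(rperm[i] + cperm[j]) % n]
            t = treatments[sym]
            rows.append({
                "plot_id": f"P{i * n + j + 1:02d}",
                "row": i + 1,
                "col": j + 1,
                "block": "",
                "cultivar_1": t[0],
                "cultivar_2": t[1] if len(t) == 2 else "",
            })
    return TrialLayout("latin_square", pd.DataFrame(rows))


def generate_rcbd(treatments: Sequence[Treatment], replicates: int, seed: int) -> TrialLayout:
    """Randomized complete block design: each block holds every treatment
    once, in seeded random order."""
    if not treatments:
        raise InvalidScenarioError("RCBD needs a non-empty treatment list")
    if replicates < 1:
        raise InvalidScenarioError("RCBD needs at least 1 replicate block")
    treatments = [as_treatment(*t) for t in treatments]
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for b in range(1, replicates + 1):
        for idx in rng.permutation(len(treatments)):
            t = treatments[idx]
            k += 1
            rows.append({
                "plot_id": f"P{k:02d}",
                "row": "",
                "col": "",
                "block": b,
                "cultivar_1": t[0],
                "cultivar_2": t[1] if len(t) == 2 else "",
            })
    return TrialLayout("rcbd", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bioassay


def generate_bioassay(scenario: BioassayScenario) -> pd.DataFrame:
    """Tube-level settling counts under the scenario's generative model.

    Each (emitter, receiver) cell gets ``tubes_per_combination`` tubes spread
    round-robin over ``pots_per_treatment`` pots; the settled count is
    binomial with success probability logistic(baseline + effect + pot
    intercept), pot intercepts shared within a pot.
    """
    rng = np.random.default_rng(scenario.seed)
    records = []
    tube_no = 0
    for (emitter, receiver) in scenario.cells():
        shift = 0.0 if emitter == CONTROL else scenario.effect_logit.get((emitter, receiver), 0.0)
        pots = [f"pot_{emitter}_{receiver}_{p + 1}" for p in range(scenario.pots_per_treatment)]
        pot_eff = rng.normal(0.0, scenario.pot_sd, size=len(pots))
        for i in range(scenario.tubes_per_combination):
            p = i % len(pots)
            eta = scenario.baseline_logit + shift + pot_eff[p]
            prob = 1.0 / (1.0 + np.exp(-eta))
            settled = int(rng.binomial(scenario.aphids_per_tube, prob))
            tube_no += 1
            records.append({
                "tube_id": f"tube_{tube_no:04d}",
                "pot_id": pots[p],
                "receiver": receiver,
                "emitter": emitter,
                "settled": settled,
                "placed": scenario.aphids_per_tube,
            })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# field measurements


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 overdispersion: Optional[float]) -> np.ndarray:
    """Negative binomial counts as a Poisson-gamma mixture; Poisson limit
    when overdispersion is None."""
    mu = np.asarray(mu, dtype=float)
    if overdispersion is None:
        return rng.poisson(mu)
    g = rng.gamma(shape=overdispersion, scale=1.0 / overdispersion, size=mu.shape)
    return rng.poisson(mu * g)


def _split_counts(rng: np.random.Generator, total: int, props: Sequence[float]) -> np.ndarray:
    return rng.multinomial(total, np.asarray(props) / np.sum(props))


def generate_field_measurements(layout: TrialLayout, scenario: FieldScenario) -> pd.DataFrame:
    """Species-level aphid counts, taxon-level natural-enemy counts and
    plot-level traits for every plot of ``layout``.

    Returns a tidy table with columns plot_id, date, variable, taxon,
    transect, value. Aphids are per transect per date (split over three
    cereal aphid species), natural enemies per plot per date (two taxa),
    traits one value per plot.
    """
    plot_treatments = layout.iter_plot_treatments()
    known = set(scenario.treatments)
    for pid, t in plot_treatments.items():
        if t not in known:
            raise InvalidScenarioError(f"plot {pid} has treatment {t!r} not in scenario")

    rng = np.random.default_rng(scenario.seed)
    plots = layout.plots
    if layout.design_kind == "latin_square":
        row_lv = sorted(plots["row"].unique())
        col_lv = sorted(plots["col"].unique())
        design_effects = [
            ("row", dict(zip(row_lv, rng.normal(0, scenario.row_sd, len(row_lv))))),
            ("col", dict(zip(col_lv, rng.normal(0, scenario.col_sd, len(col_lv))))),
        ]
    else:
        blk_lv = sorted(plots["block"].unique())
        design_effects = [
            ("block", dict(zip(blk_lv, rng.normal(0, scenario.block_sd, len(blk_lv))))),
        ]
    date_eff = dict(zip(scenario.dates, rng.normal(0, scenario.date_sd, len(scenario.dates))))
    plot_eff = dict(zip(plots["plot_id"], rng.normal(0, scenario.plot_sd, len(plots))))
    # additive raw-scale design effects for trait variables, drawn per level
    trait_eff: dict = {}
    for var in TRAIT_VARIABLES:
        dsd = scenario.trait_design_sd.get(var, 0.0)
        trait_eff[var] = [
            (col, dict(zip(effs, rng.normal(0, dsd, len(effs)))))
            for col, effs in design_effects] if dsd > 0 else []

    records = []

    def design_shift(rec) -> float:
        return sum(effs[getattr(rec, col)] for col, effs in design_effects)

    for rec in plots.itertuples(index=False):
        t = plot_treatments[rec.plot_id]
        base_shift = design_shift(rec) + plot_eff[rec.plot_id]
        aphid_mu0 = scenario.treatment_mean(t, scenario.cultivar_mean, scenario.mixture_multiplier)
        enemy_means = {c: scenario.enemy_mean for c in scenario.cultivars}
        enemy_mu0 = scenario.treatment_mean(t, enemy_means, scenario.enemy_multiplier)
        for date in scenario.dates:
            log_shift = base_shift + date_eff[date]
            # aphids: per transect, split over species
            mu = aphid_mu0 * np.exp(log_shift)
            totals = _draw_counts(rng, np.full(scenario.transects_per_plot, mu),
                                  scenario.overdispersion)
            for tr, total in enumerate(totals, start=1):
                for sp, cnt in zip(APHID_SPECIES, _split_counts(rng, int(total), APHID_SPECIES_PROPS)):
                    records.append((rec.plot_id, date, "aphids", sp, tr, int(cnt)))
            # natural enemies: per plot, split over taxa
            emu = enemy_mu0 * np.exp(log_shift)
            etotal = int(_draw_counts(rng, np.array([emu]), scenario.overdispersion)[0])
            for tx, cnt in zip(ENEMY_TAXA, _split_counts(rng, etotal, ENEMY_TAXA_PROPS)):
                records.append((rec.plot_id, date, "natural_enemies", tx, "", int(cnt)))
        # traits: one value per plot, additive Gaussian on the trait's scale
        for var in TRAIT_VARIABLES:
            means = scenario.trait_means.get(var, None)
            if means is None:
                means = {c: scenario.DEFAULT_TRAIT_MEANS[var] for c in scenario.cultivars}
            mult = scenario.trait_multiplier.get(var, {})
            mult = {as_treatment(*k): v for k, v in mult.items()}
            mean = scenario.treatment_mean(t, means, mult)
            mean += sum(effs[getattr(rec, col)] for col, effs in trait_eff[var])
            sd = scenario.trait_sd.get(var, scenario.DEFAULT_TRAIT_SD[var])
            value = float(rng.normal(mean, sd)) if sd > 0 else mean
            records.append((rec.plot_id, "", var, "", "", value))

    return pd.DataFrame(records, columns=["plot_id", "date", "variable", "taxon",
                                          "transect", "value"])


def ground_truth(scenario: FieldScenario) -> dict:
    """JSON-serializable sidecar of the scenario's true parameters."""
    return {
        "cultivar_mean": dict(scenario.cultivar_mean),
        "mixture_multiplier": {treatment_label(k): v for k, v in scenario.mixture_multiplier.items()},
        "enemy_mean": scenario.enemy_mean,
        "overdispersion": scenario.overdispersion,
        "variance_components": {
            "row_sd": scenario.row_sd, "col_sd": scenario.col_sd,
            "block_sd": scenario.block_sd, "date_sd": scenario.date_sd,
            "plot_sd": scenario.plot_sd,
        },
        "seed": scenario.seed,
    }
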