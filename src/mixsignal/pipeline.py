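"""End-to-end orchestration: screening -> field analysis -> meta-analysis.

Ties the stages into one reproducible run over either simulated study
scenarios (several country panels, several field trials) or CSV inputs,
with schema validation, stage-tagged logging to stderr, and a machine-
readable run report whose manifest hashes make determinism checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fieldtrial, meta, screening, simulate
from .errors import PipelineStageError, SchemaError
from .simulate import (BioassayScenario, FieldScenario, TrialLayout,
                       as_treatment, treatment_label)

log = logging.getLogger("mixsignal")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _log(stage: str, msg: str):
    log.info(msg, extra={"stage": stage})


# ---------------------------------------------------------------------------
# validated I/O

BIOASSAY_COLUMNS = ["tube_id", "pot_id", "receiver", "emitter", "settled", "placed"]
LAYOUT_COLUMNS = ["plot_id", "design", "row", "col", "block", "cultivar_1", "cultivar_2"]
FIELD_COLUMNS = ["plot_id", "date", "variable", "taxon", "transect", "value"]


def read_bioassay(path: str | Path) -> pd.DataFrame:
    """Read and validate a tube-level bioassay table."""
    df = _read_csv(path, BIOASSAY_COLUMNS)
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        if not (0 <= rec.settled <= rec.placed):
            raise SchemaError(f"{path}, line {i}: settled={rec.settled} outside "
                              f"[0, placed={rec.placed}]")
    return df


def read_layout(path: str | Path) -> TrialLayout:
    df = _read_csv(path, LAYOUT_COLUMNS)
    kinds = set(df["design"].astype(str))
    if len(kinds) != 1:
        raise SchemaError(f"{path}: layout mixes design kinds {sorted(kinds)}")
    df = df.fillna({"row": "", "col": "", "block": "", "cultivar_2": ""})
    return TrialLayout(kinds.pop(), df.drop(columns=["design"]))


def read_field(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, FIELD_COLUMNS)
    df = df.fillna({"date": "", "taxon": "", "transect": ""})
    counts = df["variable"].isin(simulate.COUNT_VARIABLES)
    neg = counts & (df["value"] < 0)
    if neg.any():
        raise SchemaError(f"{path}, line {int(df.index[neg][0]) + 2}: negative count")
    return df


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(columns)
    missing = set(columns) - set(df.columns)
    if unknown or missing:
        raise SchemaError(f"{path}: unknown columns {sorted(unknown)}, "
                          f"missing columns {sorted(missing)}")
    return df[list(columns)]


def write_layout(layout: TrialLayout, path: str | Path):
    df = layout.plots.copy()
    df.insert(1, "design", layout.design_kind)
    df.to_csv(path, index=False)


def read_tables(bioassay: Optional[str | Path] = None,
                layout: Optional[str | Path] = None,
                field: Optional[str | Path] = None) -> dict:
    """Read whichever inputs are given, fully validated."""
    out = {}
    if bioassay is not None:
        out["bioassay"] = read_bioassay(bioassay)
    if layout is not None:
        out["layout"] = read_layout(layout)
    if field is not None:
        out["field"] = read_field(field)
    return out


# ---------------------------------------------------------------------------
# study scenarios


@dataclass
class TrialSpec:
    """One field trial of a study scenario."""

    country: str
    year: str
    crop: str
    scenario: FieldScenario
    design_kind: str = "latin_square"
    replicates: int = 6  # RCBD only

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.country, self.year, self.crop)


@dataclass
class StudyScenario:
    """A multi-country study: one bioassay panel per (country, crop) and a
    list of field trials."""

    panels: list[Tuple[str, str, BioassayScenario]]  # (country, crop, scenario)
    trials: list[TrialSpec]


def example_study(seed: int = 0, years: Sequence[str] = ("2020", "2021"),
                  two_way_multiplier: float = 0.5,
                  priming_logit: float = -2.0) -> StudyScenario:
    """Three-country synthetic study with known ground truth.

    One panel per country, three cultivars each. In country A one pair
    interacts two-way (both exposure directions prime, settling log-odds
    shifted by ``priming_logit``) and only that pair suppresses field
    aphids (``two_way_multiplier`` < 1); country B has a one-way pair and
    country C none, both with no true field effect.
    """
    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] % (2 ** 31) for s in ss.spawn(64))
    panels_def = [
        ("CountryA", "spring_barley", ("Aria", "Borea", "Ceres"),
         {("Aria", "Borea"): "two_way"}),
        ("CountryB", "winter_wheat", ("Dana", "Elva", "Frida"),
         {("Dana", "Elva"): "one_way"}),
        ("CountryC", "spring_barley", ("Gerd", "Hilda", "Ines"),
         {("Gerd", "Hilda"): "one_way"}),
    ]
    panels, trials = [], []
    for country, crop, cultivars, interactions in panels_def:
        effect = {}
        mult = {}
        for (a, b), kind in interactions.items():
            effect[(a, b)] = priming_logit
            if kind == "two_way":
                effect[(b, a)] = priming_logit
                mult[as_treatment(a, b)] = two_way_multiplier
        panels.append((country, crop, BioassayScenario(
            receivers=cultivars, effect_logit=effect, baseline_logit=1.5,
            pot_sd=0.25, tubes_per_combination=8, pots_per_treatment=4,
            seed=next(seeds))))
        for year in years:
            trials.append(TrialSpec(country, year, crop, FieldScenario(
                cultivars=cultivars, cultivar_mean={c: 30.0 for c in cultivars},
                mixture_multiplier=mult, overdispersion=None,
                row_sd=0.04, col_sd=0.04, plot_sd=0.04,
                seed=next(seeds))))
    return StudyScenario(panels, trials)


def scenario_from_toml(path: str | Path) -> StudyScenario:
    """Load a study scenario from a TOML file.

    Expected shape::

        [[panels]]
        country = "CountryA"
        crop = "spring_barley"
        cultivars = ["Aria", "Borea", "Ceres"]
        baseline_logit = 1.5          # optional
        pot_sd = 0.3                  # optional
        [panels.effects]              # optional (emitter -> receiver shifts)
        "Aria>Borea" = -2.0

        [[trials]]
        country = "CountryA"
        year = "2021"
        crop = "spring_barley"
        cultivars = ["Aria", "Borea", "Ceres"]
        design = "latin_square"       # or "rcbd"
        replicates = 6                # rcbd only
        mean = 20.0                   # aphids per transect, all cultivars
        [trials.multipliers]          # optional mixture multipliers
        "Aria+Borea" = 0.5
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    panels = []
    for p in doc.get("panels", []):
        effects = {}
        for key, shift in p.get("effects", {}).items():
            emitter, receiver = key.split(">")
            effects[(emitter.strip(), receiver.strip())] = float(shift)
        kws = {k: p[k] for k in ("baseline_logit", "pot_sd", "aphids_per_tube",
                                 "tubes_per_combination", "pots_per_treatment")
               if k in p}
        panels.append((p["country"], p["crop"], BioassayScenario(
            receivers=tuple(p["cultivars"]), effect_logit=effects, **kws)))
    trials = []
    for t in doc.get("trials", []):
        mult = {as_treatment(*k.split("+")): float(v)
                for k, v in t.get("multipliers", {}).items()}
        mean = float(t.get("mean", 8.0))
        fs = FieldScenario(cultivars=tuple(t["cultivars"]),
                           cultivar_mean={c: mean for c in t["cultivars"]},
                           mixture_multiplier=mult,
                           **{k: t[k] for k in ("row_sd", "col_sd", "block_sd",
                                                "date_sd", "plot_sd",
                                                "overdispersion",
                                                "transects_per_plot") if k in t})
        trials.append(TrialSpec(t["country"], str(t["year"]), t["crop"], fs,
                                design_kind=t.get("design", "latin_square"),
                                replicates=int(t.get("replicates", 6))))
    if not trials:
        raise SchemaError(f"{path}: scenario defines no trials")
    return StudyScenario(panels, trials)


def config_from_toml(path: str | Path, **overrides) -> "PipelineConfig":
    """Build a PipelineConfig from a TOML file; keyword arguments override
    file values. A ``scenario`` key names a scenario TOML to simulate."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    scenario = doc.pop("scenario", None)
    kws = {k: doc[k] for k in ("out_dir", "seed", "alpha", "adjust",
                               "variables", "peak_window", "per_pair")
           if k in doc}
    kws.update(overrides)
    if scenario is not None and "scenario" not in kws:
        base = Path(path).parent
        kws["scenario"] = scenario_from_toml(base / scenario)
    return PipelineConfig(**kws)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    out_dir: str | Path = "mixsignal_out"
    seed: int = 0
    alpha: float = 0.05
    adjust: str = "none"  # none | bonferroni
    variables: Sequence[str] = ("aphids",)
    peak_window: int = 3
    per_pair: bool = False
    scenario: Optional[StudyScenario] = None
    # file-based alternative to a scenario:
    bioassay_path: Optional[str | Path] = None
    trial_paths: Sequence[Tuple[str | Path, str | Path, str, str, str]] = ()
    # (layout, field, country, year, crop)
    write_outputs: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise SchemaError("alpha must be in (0, 1)")
        if self.peak_window < 1:
            raise SchemaError("peak_window must be >= 1")
        if self.adjust not in ("none", "bonferroni"):
            raise SchemaError(f"unknown adjustment {self.adjust!r}")


@dataclass
class RunReport:
    record_counts: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)
    convergence: dict = dc_field(default_factory=dict)
    manifest: dict = dc_field(default_factory=dict)
    meta_summary: dict = dc_field(default_factory=dict)
    effects: Optional[pd.DataFrame] = None
    classifications: list = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {"record_counts": self.record_counts, "warnings": self.warnings,
                "convergence": self.convergence, "manifest": self.manifest,
                "meta_summary": self.meta_summary}


def _write(df_or_obj, path: Path, report: RunReport):
    if isinstance(df_or_obj, pd.DataFrame):
        df_or_obj.to_csv(path, index=False)
    else:
        path.write_text(json.dumps(df_or_obj, indent=2, default=float) + "\n")
    report.manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute screen -> aggregate/peak-select -> expected-mixture ->
    mixture models -> effect table -> category join -> meta-analysis."""
    import warnings as _warnings

    report = RunReport()
    out = Path(config.out_dir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    seeds = iter(s.generate_state(1)[0] % (2 ** 31) for s in ss.spawn(256))

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")

        # -- stage: inputs -------------------------------------------------
        stage = "inputs"
        try:
            panels: list[Tuple[str, str, pd.DataFrame]] = []
            trials: list[Tuple[TrialLayout, pd.DataFrame, Tuple[str, str, str]]] = []
            if config.scenario is not None:
                for country, crop, bs in config.scenario.panels:
                    bs.seed = next(seeds)
                    panels.append((country, crop, simulate.generate_bioassay(bs)))
                for trial_spec in config.scenario.trials:
                    trial_spec.scenario.seed = next(seeds)
                    if trial_spec.design_kind == "latin_square":
                        layout = simulate.generate_latin_square(
                            len(trial_spec.scenario.treatments), next(seeds),
                            treatments=trial_spec.scenario.treatments)
                    else:
                        layout = simulate.generate_rcbd(
                            trial_spec.scenario.treatments, trial_spec.replicates,
                            next(seeds))
                    data = simulate.generate_field_measurements(
                        layout, trial_spec.scenario)
                    trials.append((layout, data, trial_spec.key))
            else:
                if config.bioassay_path:
                    panels.append(("", "", read_bioassay(config.bioassay_path)))
                for (lp, fp, country, year, crop) in config.trial_paths:
                    trials.append((read_layout(lp), read_field(fp),
                                   (country, year, crop)))
            if not trials:
                raise PipelineStageError(stage, "no field trials to analyze")
            for layout, data, key in trials:
                if data.empty:
                    raise PipelineStageError("field", f"trial {key}: empty field data")
            report.record_counts["bioassay_tubes"] = int(sum(len(p[2]) for p in panels))
            report.record_counts["field_records"] = int(sum(len(t[1]) for t in trials))
            _log(stage, f"{len(panels)} bioassay panel(s), {len(trials)} trial(s)")
            if config.write_outputs:
                for country, crop, df in panels:
                    _write(df, out / f"bioassay_{country or 'input'}.csv", report)
                for layout, data, key in trials:
                    tag = "_".join(k for k in key if k) or "input"
                    write_layout(layout, out / f"layout_{tag}.csv")
                    report.manifest[f"layout_{tag}.csv"] = hashlib.sha256(
                        (out / f"layout_{tag}.csv").read_bytes()).hexdigest()
                    _write(data, out / f"field_{tag}.csv", report)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

        # -- stage: screen ------------------------------------------------
        stage = "screen"
        try:
            classifications = []
            test_tables = []
            for country, crop, df in panels:
                cls, tests = screening.screen_bioassay(
                    df, alpha=config.alpha, adjust=config.adjust)
                classifications.extend(cls)
                tests.insert(0, "country", country)
                test_tables.append(tests)
            report.classifications = classifications
            report.record_counts["directional_tests"] = int(
                sum(len(t) for t in test_tables))
            report.record_counts["pairs_classified"] = len(classifications)
            _log(stage, f"{len(classifications)} pairs classified")
            if config.write_outputs and test_tables:
                _write(pd.concat(test_tables, ignore_index=True),
                       out / "directional_tests.csv", report)
                _write(screening.classifications_table(classifications),
                       out / "pair_classifications.csv", report)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

        # -- stage: field ---------------------------------------------------
        stage = "field"
        try:
            all_effects = []
            expected_rows = []
            for layout, data, key in trials:
                agg = fieldtrial.aggregate_counts(data)
                agg = fieldtrial.select_peak_window(agg, k=config.peak_window)
                for pair in [t for t in layout.treatments() if len(t) == 2]:
                    for var in config.variables:
                        ev = fieldtrial.expected_mixture(layout, agg, pair, var)
                        df = fieldtrial.expected_table(ev)
                        df.insert(0, "variable", var)
                        for k_, v_ in zip(("country", "year", "crop"), key):
                            df.insert(0, k_, v_)
                        expected_rows.append(df)
                effects, fits = fieldtrial.analyze_trial(
                    layout, data, variables=config.variables, trial=key,
                    peak_window=config.peak_window, per_pair=config.per_pair)
                all_effects.extend(effects)
                for f in fits:
                    report.convergence[f"{'_'.join(key)}:{f.model.variable}"] = {
                        "model_kind": f.model_kind, "converged": f.converged}
            effects_df = fieldtrial.effects_table(all_effects)
            report.effects = effects_df
            report.record_counts["mixture_effects"] = len(effects_df)
            _log(stage, f"{len(effects_df)} mixture effects extracted")
            if config.write_outputs:
                _write(pd.concat(expected_rows, ignore_index=True),
                       out / "expected.csv", report)
                _write(effects_df, out / "effects.csv", report)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

        # -- stage: meta ----------------------------------------------------
        stage = "meta"
        try:
            joined, excluded = meta.category_join(effects_df, classifications)
            report.record_counts["effects_with_category"] = len(joined)
            if excluded:
                report.warnings.append(f"unclassified pairs excluded: {excluded}")
            summaries = {}
            for var in config.variables:
                sub = joined[joined["variable"] == var]
                if len(sub) < 2:
                    report.warnings.append(f"too few effects for meta-analysis of {var}")
                    continue
                global_fit = meta.fit_multilevel_meta(sub)
                mod_fit = (meta.fit_multilevel_meta(sub, moderator="category")
                           if sub["category"].nunique() > 1 else None)
                summaries[var] = {"global": global_fit.to_dict()}
                if mod_fit is not None:
                    summaries[var]["moderator"] = mod_fit.to_dict()
            report.meta_summary = summaries
            _log(stage, f"meta-analysis done for {sorted(summaries)}")
            if config.write_outputs:
                _write(summaries, out / "meta_summary.json", report)
                _write(meta.forest_data(joined), out / "forest_data.csv", report)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

        for w in caught:
            report.warnings.append(str(w.message))

    if config.write_outputs:
        _write(report.to_dict(), out / "report.json", report)
    return report
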