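"""Field analysis: aggregation, peak window, expected mixtures, models."""

import numpy as np
import pandas as pd
import patsy
import pytest
from hypothesis import given, settings, strategies as st

import mixsignal as mx
from mixsignal import fieldtrial as ft
from mixsignal.errors import (IncompleteDesignError, InvalidIntervalError,
                              ModelInputError, StandardizationError)
from conftest import scan_source_plots


def _record(plot, date, var, taxon, transect, value):
    return {"plot_id": plot, "date": date, "variable": var, "taxon": taxon,
            "transect": transect, "value": value}


class TestEffectSizeSE:
    @pytest.mark.parametrize("lo,hi,expected", [
        (-1.96, 1.96, 1.0),
        (0.0, 0.0, 0.0),
        (-0.5, 0.3, 0.8 / 3.92),
    ])
    def test_formula(self, lo, hi, expected):
        assert ft.effect_size_se(lo, hi) == pytest.approx(expected)

    def test_reversed_interval(self):
        with pytest.raises(InvalidIntervalError):
            ft.effect_size_se(0.5, -0.5)


class TestAggregation:
    def test_species_summed_per_transect_and_taxa_per_plot(self):
        raw = pd.DataFrame([
            _record("P1", "d1", "aphids", "R_padi", 1, 2),
            _record("P1", "d1", "aphids", "M_dirhodum", 1, 0),
            _record("P1", "d1", "aphids", "S_avenae", 1, 5),
            _record("P1", "d1", "natural_enemies", "Coccinellidae", "", 1),
            _record("P1", "d1", "natural_enemies", "Syrphidae", "", 2),
            _record("P1", "", "height", "", "", 83.0),
        ])
        agg = ft.aggregate_counts(raw)
        aph = agg[agg.variable == "aphids"]
        assert len(aph) == 1 and aph["value"].iloc[0] == 7
        ene = agg[agg.variable == "natural_enemies"]
        assert len(ene) == 1 and ene["value"].iloc[0] == 3
        ht = agg[agg.variable == "height"]
        assert len(ht) == 1 and ht["value"].iloc[0] == 83.0

    def test_empty_input(self):
        assert ft.aggregate_counts(pd.DataFrame(
            columns=["plot_id", "date", "variable", "taxon", "transect", "value"])).empty

    def test_round_trip_leaves_other_variables_untouched(self):
        fs = mx.FieldScenario(cultivars=("A", "B"), seed=4)
        layout = mx.generate_rcbd(fs.treatments, 2, seed=4)
        raw = mx.generate_field_measurements(layout, fs)
        agg = ft.aggregate_counts(raw)
        traits_before = raw[raw.variable == "yield"].sort_values("plot_id")
        traits_after = agg[agg.variable == "yield"].sort_values("plot_id")
        assert np.allclose(traits_before["value"].to_numpy(),
                           traits_after["value"].to_numpy())


class TestPeakWindow:
    @staticmethod
    def _dataset(totals):
        rows = [_record("P1", f"2021-06-{d + 1:02d}", "aphids", "", 1, v)
                for d, v in enumerate(totals)]
        return pd.DataFrame(rows)

    def test_window_around_peak_matches_brute_force(self):
        data = self._dataset([1, 5, 40, 60, 30, 2])
        kept = sorted(ft.select_peak_window(data, k=3)["date"].unique())
        # brute force over every width-3 window containing the peak date
        totals = [1, 5, 40, 60, 30, 2]
        dates = sorted(data["date"].unique())
        best = max((s for s in range(4) if s <= 3 <= s + 2),
                   key=lambda s: sum(totals[s:s + 3]))
        assert kept == dates[best:best + 3]
        assert kept == ["2021-06-03", "2021-06-04", "2021-06-05"]

    def test_fewer_dates_than_window(self):
        data = self._dataset([3, 9])
        assert ft.select_peak_window(data, k=3)["date"].nunique() == 2

    def test_tie_keeps_earliest_window(self):
        data = self._dataset([4, 4, 4, 4, 4])
        kept = sorted(ft.select_peak_window(data, k=3)["date"].unique())
        assert kept == ["2021-06-01", "2021-06-02", "2021-06-03"]

    def test_window_applied_to_enemies_only_dated_variables(self):
        rows = [_record("P1", f"d{d}", "aphids", "", 1, v)
                for d, v in enumerate([1, 10, 20, 30, 2])]
        rows += [_record("P1", f"d{d}", "natural_enemies", "", "", 1)
                 for d in range(5)]
        rows += [_record("P1", "", "tgw", "", "", 44.0)]
        out = ft.select_peak_window(pd.DataFrame(rows), k=3)
        assert out[out.variable == "natural_enemies"]["date"].nunique() == 3
        assert len(out[out.variable == "tgw"]) == 1


class TestExpectedMixture:
    def test_constant_field_gives_constant_expectation(self):
        treatments = [("A",), ("B",), ("A", "B")]
        layout = mx.generate_latin_square(3, seed=1, treatments=treatments)
        rows = [_record(p, "", "yield", "", "", 8.0) for p in layout.plots["plot_id"]]
        vals = ft.expected_mixture(layout, pd.DataFrame(rows), ("A", "B"), "yield")
        assert len(vals) == 3
        assert all(v.value == pytest.approx(8.0) for v in vals)
        assert all(len(v.source_plots) == 4 for v in vals)

    def test_known_source_values_average(self):
        """Four known source values 2,4,6,8 average to 5, and the sources
        match an exhaustive same-row/same-column scan."""
        treatments = ([("A",), ("B",), ("C",)]
                      + [("A", "B"), ("A", "C"), ("B", "C")])
        layout = mx.generate_latin_square(6, seed=11, treatments=treatments)
        tmap = layout.iter_plot_treatments()
        mix_plot = next(p for p, t in tmap.items() if t == ("A", "B"))
        sources = scan_source_plots(layout, mix_plot, ("A", "B"))
        values = {p: v for p, v in zip(sorted(sources), [2.0, 4.0, 6.0, 8.0])}
        rows = [_record(p, "", "yield", "", "", values.get(p, 1.0))
                for p in layout.plots["plot_id"]]
        vals = ft.expected_mixture(layout, pd.DataFrame(rows), ("A", "B"), "yield")
        target = next(v for v in vals if v.mixture_plot == mix_plot)
        assert target.value == pytest.approx(5.0)
        assert set(target.source_plots) == sources

    def test_rcbd_block_mean(self):
        layout = mx.generate_rcbd([("A",), ("B",), ("A", "B")], 1, seed=0)
        tmap = layout.iter_plot_treatments()
        values = {p: {("A",): 3.0, ("B",): 5.0, ("A", "B"): 9.0}[t]
                  for p, t in tmap.items()}
        rows = [_record(p, "", "yield", "", "", v) for p, v in values.items()]
        vals = ft.expected_mixture(layout, pd.DataFrame(rows), ("A", "B"), "yield")
        assert len(vals) == 1 and vals[0].value == pytest.approx(4.0)
        assert len(vals[0].source_plots) == 2

    def test_missing_monoculture_is_a_hard_error(self):
        layout = mx.generate_rcbd([("A",), ("A", "B")], 1, seed=0)
        rows = [_record(p, "", "yield", "", "", 1.0) for p in layout.plots["plot_id"]]
        with pytest.raises(IncompleteDesignError, match="monoculture B"):
            ft.expected_mixture(layout, pd.DataFrame(rows), ("A", "B"), "yield")

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_sources_match_exhaustive_scan_on_random_squares(self, seed):
        treatments = ([("A",), ("B",), ("C",)]
                      + [("A", "B"), ("A", "C"), ("B", "C")])
        layout = mx.generate_latin_square(6, seed=seed, treatments=treatments)
        rows = [_record(p, "", "yield", "", "", 1.0) for p in layout.plots["plot_id"]]
        data = pd.DataFrame(rows)
        for pair in [("A", "B"), ("A", "C"), ("B", "C")]:
            for v in ft.expected_mixture(layout, data, pair, "yield"):
                assert len(v.source_plots) == 4
                assert set(v.source_plots) == scan_source_plots(
                    layout, v.mixture_plot, pair)


class TestMixtureModel:
    @staticmethod
    def _trial(seed, multiplier=1.0, **scenario_kws):
        fs = mx.FieldScenario(cultivars=("A", "B", "C"),
                              mixture_multiplier={("A", "B"): multiplier},
                              seed=seed, **scenario_kws)
        layout = mx.generate_latin_square(6, seed + 1, treatments=fs.treatments)
        data = mx.generate_field_measurements(layout, fs)
        return layout, ft.select_peak_window(ft.aggregate_counts(data))

    def test_zero_variance_triggers_fallback_matching_ols(self):
        """With no row/col/date variability the mixed fit is singular; the
        fallback must match an independent least-squares solve to 1e-6."""
        layout, data = self._trial(1, row_sd=0, col_sd=0, date_sd=0, plot_sd=0)
        res = ft.MixtureModel.from_trial(layout, data, "aphids").fit()
        assert res.model_kind == "fixed_fallback"
        frame = res.model.frame
        y, X = patsy.dmatrices(res.model._fallback_formula(), frame,
                               return_type="dataframe")
        beta, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy().ravel(), rcond=None)
        oracle = dict(zip(X.columns, beta))
        est, _ = res.coefficient("A+B")
        name = res._param_name("A+B")
        assert est == pytest.approx(oracle[name], abs=1e-6)

    def test_observed_equals_expected_gives_null_effect(self):
        frame = pd.DataFrame({
            "pair": ["A+B"] * 12, "vtype": ["observed", "expected"] * 6,
            "value": np.repeat(np.arange(6), 2) + 3.0,
            "block": np.repeat(np.arange(6), 2),
        })
        res = ft.fit_mixture_model(frame, "rcbd", "yield")
        est, lo, hi = res.coefficient_ci("A+B")
        assert est == pytest.approx(0.0, abs=1e-8)
        assert lo <= 0 <= hi

    def test_needs_both_value_types(self):
        frame = pd.DataFrame({"pair": ["A+B"] * 4, "vtype": ["observed"] * 4,
                              "value": [1.0, 2, 3, 4], "block": [1, 1, 2, 2]})
        with pytest.raises(ModelInputError):
            ft.MixtureModel(frame, "rcbd", "yield")

    def test_aphid_suppression_power(self):
        """A true halving of aphid counts gives a negative observed-vs-
        expected coefficient in >=90% of 200 simulated trials."""
        neg = 0
        for i in range(200):
            layout, data = self._trial(10_000 + 3 * i, multiplier=0.5)
            res = ft.MixtureModel.from_trial(layout, data, "aphids").fit()
            est, _ = res.coefficient("A+B")
            neg += est < 0
        assert neg >= 180

    def test_standardized_coefficient_properties(self):
        layout, data = self._trial(77)
        res = ft.MixtureModel.from_trial(layout, data, "aphids").fit()
        sd = res.model.frame["y"].std(ddof=1)
        for pair in res.model.pairs:
            raw, _ = res.coefficient(pair)
            eff = res.standardized_coefficient(pair)
            # beta/s scaling, exact for the refit-on-scaled-response route
            assert eff.coefficient == pytest.approx(raw / sd, abs=1e-8)
            assert np.sign(eff.coefficient) == np.sign(raw)
            assert eff.ci_low <= eff.coefficient <= eff.ci_high
            assert eff.se == pytest.approx((eff.ci_high - eff.ci_low) / 3.92)

    def test_standardization_needs_response_variance(self):
        frame = pd.DataFrame({
            "pair": ["A+B"] * 8, "vtype": ["observed", "expected"] * 4,
            "value": 5.0, "block": np.repeat(np.arange(4), 2)})
        res = ft.fit_mixture_model(frame, "rcbd", "yield")
        with pytest.raises(StandardizationError):
            res.standardized_coefficient("A+B")

    def test_diagnostics_reported(self):
        layout, data = self._trial(5)
        res = ft.MixtureModel.from_trial(layout, data, "aphids").fit()
        diag = res.diagnostics()
        assert 0 < diag["qq_correlation"] <= 1


class TestRecovery:
    def test_no_effect_centring_and_coverage(self):
        """With multiplier 1 the standardized coefficients are centred on 0
        and their 95% CIs cover 0 at the nominal rate (untransformed trait
        response, per-pair refits on an 8-block RCBD)."""
        coefs, cover = [], 0
        for i in range(400):
            fs = mx.FieldScenario(cultivars=("A", "B"),
                                  trait_sd={"yield": 300.0},
                                  trait_design_sd={"yield": 150.0},
                                  seed=810_000 + i)
            layout = mx.generate_rcbd(fs.treatments, 8, 910_000 + i)
            data = mx.generate_field_measurements(layout, fs)
            res = ft.MixtureModel.from_trial(layout, data, "yield").fit()
            e = res.standardized_coefficient("A+B")
            coefs.append(e.coefficient)
            cover += (e.ci_low <= 0 <= e.ci_high)
        coefs = np.asarray(coefs)
        mc_se = coefs.std(ddof=1) / np.sqrt(len(coefs))
        assert abs(coefs.mean()) < 3 * mc_se
        band = 3 * np.sqrt(0.95 * 0.05 / len(coefs))
        assert cover / len(coefs) > 0.95 - band

    def test_halving_recovered_with_bounded_bias(self):
        """With a known 0.5 multiplier the median standardized coefficient
        is negative, and the back-transformed effect's bias (log(x+1)
        scale vs the generative truth) is bounded."""
        raw, std = [], []
        truth = np.log1p(0.5 * 30.0) - np.log1p(30.0)
        for i in range(100):
            fs = mx.FieldScenario(cultivars=("A", "B", "C"),
                                  cultivar_mean={c: 30.0 for c in "ABC"},
                                  mixture_multiplier={("A", "B"): 0.5},
                                  overdispersion=None,
                                  row_sd=0.04, col_sd=0.04, plot_sd=0.04,
                                  seed=40_000 + i)
            layout = mx.generate_latin_square(6, 41_000 + i, treatments=fs.treatments)
            data = mx.generate_field_measurements(layout, fs)
            agg = ft.select_peak_window(ft.aggregate_counts(data))
            res = ft.MixtureModel.from_trial(layout, agg, "aphids",
                                             pairs=[("A", "B")]).fit()
            est, _ = res.coefficient("A+B")
            raw.append(est)
            std.append(res.standardized_coefficient("A+B").coefficient)
        assert np.median(std) < 0
        bias = np.mean(raw) - truth
        assert abs(bias) < 0.1  # log(x+1)-scale bias bound at these settings
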