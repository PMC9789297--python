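import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from abrlab.containers import AverageResponse
from abrlab.simulate import SimCohortSpec, one_cycle_sine, simulate_latency_table
from abrlab.stats import (
    adjust_chirp_latencies,
    aggregate_amplitude,
    bootstrap_se,
    chirp_benefit,
    compare_models,
    fit_dispersion,
    heteroscedastic_reweight,
    power_two_sample,
    tmax_permutation,
)

FS = 16_384.0


class TestAdjustChirpLatencies:
    def _table(self, offset):
        rows = []
        for s in ("a", "b"):
            for f in (1.0, 4.0):
                base = 5.0 + f
                rows.append({"subject": s, "wave": "V", "profile": "white",
                             "band": f, "f": f, "stimulus": "click",
                             "latency_ms": base})
                rows.append({"subject": s, "wave": "V", "profile": "white",
                             "band": f, "f": f, "stimulus": "chirp",
                             "latency_ms": base - offset})
        return pd.DataFrame(rows)

    def test_identical_latencies_need_no_adjustment(self):
        out = adjust_chirp_latencies(self._table(0.0))
        assert out.attrs["chirp_adjustment_ms"] == pytest.approx(0.0)
        pd.testing.assert_frame_equal(out, self._table(0.0))

    def test_constant_offset_fully_removed(self):
        out = adjust_chirp_latencies(self._table(2.5))
        assert out.attrs["chirp_adjustment_ms"] == pytest.approx(2.5)
        wide = out.pivot_table(index=["subject", "band"], columns="stimulus",
                               values="latency_ms")
        assert np.allclose(wide["click"], wide["chirp"])

    def test_mixed_offsets_balance_to_zero_mean_difference(self):
        tab = self._table(1.0)
        rng = np.random.default_rng(0)
        tab.loc[tab.stimulus == "chirp", "latency_ms"] += rng.normal(
            0, 0.3, (tab.stimulus == "chirp").sum())
        out = adjust_chirp_latencies(tab)
        wide = out.pivot_table(index=["subject", "band"], columns="stimulus",
                               values="latency_ms")
        assert (wide["click"] - wide["chirp"]).mean() == pytest.approx(
            0.0, abs=1e-12)

    def test_missing_stimulus_kind_rejected(self):
        tab = self._table(1.0)
        with pytest.raises(ValueError):
            adjust_chirp_latencies(tab[tab.stimulus == "click"])


class TestCompareModels:
    @pytest.fixture(scope="class")
    def table(self):
        spec = SimCohortSpec(n_F=6, n_M=6, u_lat_sd=0.2, sex_waveV_offset=0.0,
                             stimuli=(("click", "white"),), seed=9)
        return simulate_latency_table(spec, lat_noise_sd=0.1, seed=10)

    def test_identical_models_give_null_result(self, table):
        a = fit_dispersion(table, strata={"A": ["wave"]})
        b = fit_dispersion(table, strata={"A": ["wave"]})
        res = compare_models(a, b)
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.pvalue == pytest.approx(1.0, abs=1e-3)
        assert res.bf == pytest.approx(1.0, rel=1e-3)

    def test_chi2_pvalue_matches_distribution_oracle(self, table):
        null = fit_dispersion(table, strata={"A": ["wave"]})
        alt = fit_dispersion(table, strata={"A": ["wave"],
                                            "K": ["wave"], "D": ["wave"]})
        res = compare_models(null, alt)
        assert res.df == 2
        assert res.statistic == pytest.approx(2 * (alt.llf - null.llf))
        assert res.pvalue == pytest.approx(
            float(sps.chi2.sf(res.statistic, res.df)))
        # reference point of the chi-squared tail: sf(20, 2) ~ 4.54e-5
        assert float(sps.chi2.sf(20.0, 2)) == pytest.approx(4.54e-5, rel=1e-3)

    def test_useless_parameters_penalized_by_bic(self, table):
        """On null-true data the richer model loses by Occam's razor."""
        null = fit_dispersion(table, strata={"A": ["wave"]})
        alt = fit_dispersion(table, strata={"A": ["wave"], "K": ["wave", "sex"],
                                            "D": ["wave", "sex"]})
        res = compare_models(null, alt)
        assert res.bf_direction == "BF01"
        assert res.bf > 1.0

    def test_non_nested_models_rejected(self, table):
        a = fit_dispersion(table, strata={"K": ["wave"]})
        b = fit_dispersion(table, strata={"D": ["sex"]})
        with pytest.raises(ValueError, match="nested"):
            compare_models(a, b)

    def test_bf_label_caps_at_150(self):
        from abrlab.stats import TestResult
        assert TestResult(bf=200.0, bf_direction="BF01").bf_label() == "BF01 > 150"
        assert TestResult(bf=3.0, bf_direction="BF10").bf_label() == "BF10 = 3"


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample(0.0, 1.0, 20, 20) == pytest.approx(0.05,
                                                                   abs=1e-6)

    def test_monotone_in_effect_and_sample_size(self):
        p1 = power_two_sample(0.3, 1.0, 10, 10)
        p2 = power_two_sample(0.6, 1.0, 10, 10)
        p3 = power_two_sample(0.6, 1.0, 40, 40)
        assert p1 < p2 < p3

    def test_normal_approximation_close_for_large_n(self):
        exact = power_two_sample(0.4, 1.0, 200, 200)
        approx = power_two_sample(0.4, 1.0, 200, 200, method="normal")
        assert approx == pytest.approx(exact, abs=5e-3)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample(1.0, 0.0, 10, 10)
        with pytest.raises(ValueError):
            power_two_sample(1.0, 1.0, 1, 10)


class TestTmax:
    def test_zero_differences_never_significant(self):
        res = tmax_permutation(np.zeros((8, 16)), n_perm=500, window_ms=None,
                               seed=0)
        assert not res.significant.any()

    def test_large_constant_offset_everywhere_significant(self):
        rng = np.random.default_rng(1)
        data = 5.0 + rng.normal(0, 0.1, size=(10, 16))
        res = tmax_permutation(data, n_perm=2000, window_ms=None, seed=2)
        assert res.significant.all()

    def test_window_selection_uses_time_axis(self):
        n = int(45e-3 * FS)
        resps = []
        rng = np.random.default_rng(3)
        for i in range(6):
            v = one_cycle_sine(-5 + np.arange(n) / FS * 1e3, 6.0, 2.0, 3.0)
            resps.append(AverageResponse(fs=FS, values=v + rng.normal(
                0, 0.2, n), t0=-5e-3))
        res = tmax_permutation(resps, n_perm=500, window_ms=(0.0, 12.0),
                               seed=4)
        assert res.times_ms.min() >= 0.0 and res.times_ms.max() <= 12.0
        assert res.significant.any()  # strong common deflection

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            tmax_permutation(np.zeros((1, 8)), n_perm=10, window_ms=None)


class TestAggregates:
    def _resp(self, values):
        return AverageResponse(fs=FS, values=values, t0=-5e-3)

    def test_zero_signal_zero_aggregate(self):
        n = int(45e-3 * FS)
        assert aggregate_amplitude(self._resp(np.zeros(n)), (2, 9)) == 0.0

    def test_rectangle_rule_on_constant(self):
        n = int(45e-3 * FS)
        agg = aggregate_amplitude(self._resp(np.ones(n)), (5.0, 9.0))
        # endpoints quantize to the sample grid: one step slack per edge
        assert agg == pytest.approx(4.0, abs=2 * 1e3 / FS)

    def test_one_cycle_sine_integral_closed_form(self):
        n = int(45e-3 * FS)
        t = -5 + np.arange(n) / FS * 1e3
        for period in (1.0, 2.0):
            v = one_cycle_sine(t, 5.0, period, 1.0)
            agg = aggregate_amplitude(self._resp(v), (2.0, 9.0))
            assert agg == pytest.approx(2 * period / np.pi, rel=5e-3)

    def test_empty_window_rejected(self):
        n = int(45e-3 * FS)
        with pytest.raises(ValueError):
            aggregate_amplitude(self._resp(np.zeros(n)), (100.0, 101.0))

    @pytest.mark.parametrize("click, chirp, expected", [
        (2.0, 2.0, 0.0),
        (2.0, 3.0, 50.0),
        (1.0, 0.64, -36.0),
    ])
    def test_chirp_benefit_arithmetic(self, click, chirp, expected):
        assert chirp_benefit(click, chirp) == pytest.approx(expected)

    def test_zero_click_amplitude_flagged(self):
        with pytest.raises(ValueError):
            chirp_benefit(0.0, 1.0)


class TestBootstrap:
    def test_constant_values_zero_se(self):
        mean, se = bootstrap_se(np.full(10, 3.0), n_boot=200, seed=0)
        assert mean == pytest.approx(3.0)
        assert se == 0.0

    def test_iid_normal_se_matches_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 2.0, 400)
        _, se = bootstrap_se(x, n_boot=2000, seed=1)
        assert se == pytest.approx(2.0 / 20.0, rel=0.1)

    def test_seeded_reproducibility(self):
        x = np.arange(12.0)
        assert bootstrap_se(x, seed=7, n_boot=100) == bootstrap_se(
            x, seed=7, n_boot=100)


class TestReweight:
    def _table(self, sd_by_level, n=60, seed=0, exact=False):
        rng = np.random.default_rng(seed)
        rows = []
        for lv, sd in sd_by_level.items():
            x = rng.normal(size=n)
            if exact:  # force the sample SD to the target exactly
                x = (x - x.mean()) / x.std(ddof=1) * sd
            else:
                x = sd * x
            rows.extend({"wave": lv, "latency_ms": v} for v in x)
        return pd.DataFrame(rows)

    def test_equal_variances_no_reweighting(self):
        w, res = heteroscedastic_reweight(self._table({"I": 1.0, "V": 1.0}),
                                          "wave")
        assert np.allclose(w, 1.0)
        assert not res.meta["weighted"]

    def test_unequal_variances_inverse_weighted(self):
        tab = self._table({"I": 1.0, "V": 2.0}, n=400, seed=1, exact=True)
        w, res = heteroscedastic_reweight(tab, "wave")
        assert res.meta["weighted"]
        w_I = w[(tab.wave == "I").to_numpy()][0]
        w_V = w[(tab.wave == "V").to_numpy()][0]
        ratio = w_I / w_V  # variances 1 vs 4 -> weights 4:1
        assert ratio == pytest.approx(4.0, rel=1e-9)

    def test_levene_equals_anova_on_absolute_deviations(self):
        tab = self._table({"I": 1.0, "V": 1.7}, n=40, seed=2)
        _, res = heteroscedastic_reweight(tab, "wave", center="mean")
        groups = [tab.loc[tab.wave == lv, "latency_ms"].to_numpy()
                  for lv in ("I", "V")]
        devs = [np.abs(g - g.mean()) for g in groups]
        f_oracle, p_oracle = sps.f_oneway(*devs)
        assert res.statistic == pytest.approx(f_oracle)
        assert res.pvalue == pytest.approx(p_oracle)

    def test_single_level_is_noop(self):
        w, res = heteroscedastic_reweight(self._table({"I": 1.0}), "wave")
        assert np.allclose(w, 1.0) and res.pvalue == 1.0
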