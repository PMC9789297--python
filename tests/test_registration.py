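import numpy as np
import pytest

from abrlab.registration import (
    WarpFunction,
    align_pair,
    individual_latencies,
    pick_peaks,
    register,
)

WINDOWS = {"I": (1.0, 5.0), "V": (4.5, 9.5)}
SAMPLE_MS = 1e3 / 16_384.0


class TestWarpFunction:
    def test_round_trip_is_identity(self):
        w = WarpFunction(knots_target=[0.0, 4.0, 8.0, 12.0],
                         knots_individual=[0.0, 4.5, 8.2, 12.0])
        t = np.linspace(0.0, 12.0, 50)
        assert np.allclose(w.to_target(w.to_individual(t)), t, atol=1e-12)

    def test_non_monotone_knots_rejected(self):
        with pytest.raises(ValueError):
            WarpFunction(knots_target=[0, 1, 2],
                         knots_individual=[0, 2, 1.5])

    def test_pick_outside_window_rejected(self):
        w = WarpFunction(knots_target=[0.0, 12.0], knots_individual=[0.0, 12.0])
        with pytest.raises(ValueError):
            w.to_individual(13.0)


@pytest.mark.filterwarnings("ignore:registration did not converge")
class TestRegister:
    def test_identical_responses_are_a_fixed_point(self, abr_template):
        rs = [abr_template(0.0) for _ in range(3)]
        res = register(rs, max_iter=4)
        for w in res.warps:
            assert np.allclose(w.knots_individual, w.knots_target, atol=0.02)
        assert np.allclose(res.structural_average.values, rs[0].values,
                           atol=1e-6)

    def test_known_shifts_recovered_within_grid_step(self, abr_template):
        rs = [abr_template(-1.0), abr_template(1.0)]
        res = register(rs, max_iter=12)
        picks = pick_peaks(res.structural_average, WINDOWS)
        lat = individual_latencies(res.warps, picks, ids=["a", "b"])
        lat_I = lat[lat.wave == "I"].set_index("subject")["latency_ms"]
        assert lat_I["a"] == pytest.approx(2.0, abs=SAMPLE_MS)
        assert lat_I["b"] == pytest.approx(4.0, abs=SAMPLE_MS)

    def test_structural_average_sharper_than_cross_sectional(self, abr_template):
        shifts = [-0.6, -0.2, 0.3, 0.7]
        rs = [abr_template(s) for s in shifts]
        res = register(rs, max_iter=12)
        cs_peak = np.mean([r.values for r in rs], axis=0).max()
        assert res.structural_average.values.max() > cs_peak * 1.2

    def test_large_penalty_forces_identity_warps(self, abr_template):
        rs = [abr_template(-0.5), abr_template(0.5)]
        res = register(rs, penalty=1e9, max_iter=3)
        for w in res.warps:
            assert np.allclose(w.knots_individual, w.knots_target, atol=0.01)
        cs = np.mean([r.values for r in rs], axis=0)
        sel = (rs[0].times_ms >= 0) & (rs[0].times_ms <= 12)
        assert np.allclose(res.structural_average.values[sel], cs[sel],
                           atol=1e-3)

    def test_warps_strictly_monotone_with_endpoint_identity(self, abr_template):
        rng = np.random.default_rng(3)
        rs = [abr_template(s, noise_sd=0.05, seed=i)
              for i, s in enumerate(rng.normal(0, 0.3, 6))]
        res = register(rs, max_iter=8)
        for w in res.warps:
            assert np.all(np.diff(w.knots_individual) > 0)
            assert w.knots_individual[0] == pytest.approx(w.knots_target[0])
            assert w.knots_individual[-1] == pytest.approx(w.knots_target[-1])

    def test_needs_at_least_two_responses(self, abr_template):
        with pytest.raises(ValueError):
            register([abr_template(0.0)])

    def test_jittered_noisy_cohort_latency_accuracy(self, abr_template):
        """Automatic latencies track truth with r >= 0.95 and MAE <= 0.15 ms."""
        rng = np.random.default_rng(12)
        shifts = rng.normal(0.0, 0.3, 12)
        rs = [abr_template(s, noise_sd=0.05, seed=100 + i)
              for i, s in enumerate(shifts)]
        res = register(rs, max_iter=12)
        picks = pick_peaks(res.structural_average, WINDOWS)
        lat = individual_latencies(res.warps, picks,
                                   ids=[str(i) for i in range(len(shifts))])
        for wave, base in (("I", 3.0), ("V", 6.5)):
            got = lat[lat.wave == wave].set_index("subject")["latency_ms"]
            got = got.loc[[str(i) for i in range(len(shifts))]].to_numpy()
            truth = base + shifts
            assert np.corrcoef(got, truth)[0, 1] >= 0.95
            assert np.mean(np.abs(got - truth)) <= 0.15


class TestPickPeaks:
    def test_noise_free_template_picked_at_truth(self, abr_template):
        picks = pick_peaks(abr_template(0.0), WINDOWS)
        assert picks["I"].peak_ms == pytest.approx(3.0, abs=SAMPLE_MS)
        assert picks["I"].trough_ms == pytest.approx(3.5, abs=SAMPLE_MS)
        assert picks["V"].peak_ms == pytest.approx(6.5, abs=SAMPLE_MS)
        assert picks["V"].trough_ms == pytest.approx(7.5, abs=SAMPLE_MS)
        assert picks["V"].peak_ms > picks["I"].peak_ms

    def test_monotone_segment_flags_missing_pick(self, abr_template):
        resp = abr_template(0.0)
        resp.values = resp.times_ms.copy()  # strictly increasing ramp
        picks = pick_peaks(resp, {"I": (1.0, 4.0)})
        assert picks["I"].missing and np.isnan(picks["I"].peak_ms)

    def test_equal_maxima_earliest_wins(self, abr_template):
        resp = abr_template(0.0)
        v = np.zeros_like(resp.values)
        t = resp.times_ms
        i1 = int(np.argmin(np.abs(t - 2.0)))
        i2 = int(np.argmin(np.abs(t - 3.0)))
        for i in (i1, i2):  # two bit-identical local maxima
            v[i - 1:i + 2] = [0.5, 1.0, 0.5]
        resp.values = v
        picks = pick_peaks(resp, {"I": (1.0, 4.0)})
        assert picks["I"].peak_ms == pytest.approx(t[i1])


class TestAlignPair:
    def test_identical_inputs_unchanged(self, abr_template):
        a = abr_template(0.0)
        b = abr_template(0.0)
        a2, b2 = align_pair(a, b, max_iter=3)
        assert np.allclose(a2.values, a.values, atol=1e-6)
        assert np.allclose(b2.values, b.values, atol=1e-6)

    def test_shifted_copies_overlap_after_alignment(self, abr_template):
        a = abr_template(-0.5)
        b = abr_template(0.5)
        a2, b2 = align_pair(a, b, max_iter=10)
        peak = np.abs(a.values).max()
        assert np.abs(a2.values - b2.values).max() < 0.1 * peak

    def test_alignment_preserves_extreme_values(self, abr_template):
        a = abr_template(-0.4)
        b = abr_template(0.4)
        a2, b2 = align_pair(a, b, max_iter=10)
        assert a2.values.max() == pytest.approx(a.values.max(), rel=0.02)
        assert b2.values.min() == pytest.approx(b.values.min(), rel=0.02)
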