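import math

import numpy as np
import pytest

from abrlab.dispersion import GroupDelayParams
from abrlab.simulate import (
    BROADBAND,
    SimCohortSpec,
    band_centre_labels,
    band_response,
    band_upper_edges,
    highpass_masked_trace,
    one_cycle_sine,
    simulate_cohort,
    simulate_epochs,
    simulate_latency_table,
    true_latency,
)


def _subject(spec, **overrides):
    subj = spec.draw_subjects(np.random.default_rng(0))[0]
    if overrides:
        from dataclasses import replace
        subj = replace(subj, **overrides)
    return subj


class TestBandStructure:
    def test_upper_edges_include_octave_extension(self):
        assert np.allclose(band_upper_edges([0.5, 1, 2, 4, 8]),
                           [0.5, 1, 2, 4, 8, 16])

    def test_centre_labels_match_octave_convention(self):
        assert band_centre_labels([0.5, 1, 2, 4, 8]).tolist() == [
            0.4, 0.7, 1.4, 2.8, 5.7, 11.3]

    def test_four_cutoff_variant(self):
        assert band_centre_labels([1, 2, 4, 8]).tolist() == [
            0.7, 1.4, 2.8, 5.7, 11.3]


class TestBandResponse:
    def test_cross_band_latency_difference_matches_dispersion_law(self):
        """Click latency difference across bands is K*(f1^-D - f2^-D)."""
        spec = SimCohortSpec(u_lat_sd=0.0, sex_waveV_offset=0.0)
        subj = _subject(spec)
        spec2 = SimCohortSpec(u_lat_sd=0.0, sex_waveV_offset=0.0,
                              cutoffs=(0.707, 5.657),
                              band_amplitudes={"I": (1.0,) * 3,
                                               "V": (1.0,) * 3})
        lat_lo = true_latency(spec2, "I", 0, "click", subj)
        lat_hi = true_latency(spec2, "I", 1, "click", subj)
        assert lat_lo - lat_hi == pytest.approx(
            4.54 * (0.707**-0.436 - 5.657**-0.436))
        assert lat_lo - lat_hi == pytest.approx(3.1482200209, abs=1e-9)

    def test_matched_chirp_cancels_dispersion_exactly(self):
        spec = SimCohortSpec(u_lat_sd=0.0, sex_waveV_offset=0.0)
        subj = _subject(spec, u_lat=0.0)
        lats = [true_latency(spec, "I", b, "chirp", subj)
                for b in range(spec.n_bands)]
        assert np.allclose(lats, spec.wave_templates["I"].base_latency)

    def test_amplitude_scales_linearly_with_subject_scalar(self):
        spec = SimCohortSpec()
        s1 = _subject(spec, u_amp=1.0)
        s2 = _subject(spec, u_amp=2.5)
        r1 = band_response("V", 3, "click", s1, spec)
        r2 = band_response("V", 3, "click", s2, spec)
        assert np.allclose(r2.samples, 2.5 * r1.samples)

    def test_latency_at_1khz_with_zero_offsets_equals_K(self):
        tmpl = {"I": SimCohortSpec().wave_templates["I"]}
        from dataclasses import replace
        tmpl["I"] = replace(tmpl["I"], base_latency=0.0)
        spec = SimCohortSpec(wave_templates=tmpl,
                             band_amplitudes={"I": (1,) * 6},
                             u_lat_sd=0.0, sex_waveV_offset=0.0)
        subj = _subject(spec, u_lat=0.0)
        # band index 1 has upper edge 1 kHz
        assert true_latency(spec, "I", 1, "click", subj) == pytest.approx(4.54)


class TestMaskedTraces:
    def test_telescoping_identity_is_exact(self, tiny_spec, tiny_cohort):
        for subj in tiny_cohort.subjects:
            bb = highpass_masked_trace(BROADBAND, subj, "click", tiny_spec)
            total = np.zeros_like(bb.samples)
            prev = np.zeros_like(bb.samples)
            for cutoff in tiny_spec.cutoffs:
                cur = highpass_masked_trace(cutoff, subj, "click",
                                            tiny_spec).samples
                total += cur - prev
                prev = cur
            total += bb.samples - prev  # top band
            assert np.array_equal(total, bb.samples)

    def test_unknown_cutoff_rejected(self, tiny_spec):
        subj = _subject(tiny_spec)
        with pytest.raises(ValueError):
            highpass_masked_trace(3.0, subj, "click", tiny_spec)

    def test_masked_below_lowest_band_would_be_empty(self):
        spec = SimCohortSpec(cutoffs=(0.5, 1.0),
                             band_amplitudes={"I": (1, 1, 1), "V": (1, 1, 1)})
        subj = _subject(spec)
        trace = highpass_masked_trace(0.5, subj, "click", spec)
        # only the lowest band contributes below the first cutoff
        single = sum(
            band_response(w, 0, "click", subj, spec).samples for w in ("I", "V"))
        assert np.allclose(trace.samples, single)


class TestEpochs:
    def test_zero_noise_replicates_trace(self, tiny_spec):
        subj = _subject(tiny_spec)
        trace = highpass_masked_trace(BROADBAND, subj, "click", tiny_spec)
        es = simulate_epochs(trace, n_epochs=5, noise_sd=0.0, seed=0)
        assert np.array_equal(es.data, np.tile(trace.samples, (5, 1)))
        assert es.polarity.tolist() == [1, -1, 1, -1, 1]

    def test_epoch_mean_converges_at_root_n(self, tiny_spec):
        subj = _subject(tiny_spec)
        trace = highpass_masked_trace(BROADBAND, subj, "click", tiny_spec)
        es = simulate_epochs(trace, n_epochs=400, noise_sd=1.0, seed=42)
        resid = es.data.mean(axis=0) - trace.samples
        assert resid.std() == pytest.approx(1.0 / 20.0, rel=0.2)

    def test_seeded_reproducibility(self, tiny_spec):
        subj = _subject(tiny_spec)
        trace = highpass_masked_trace(8.0, subj, "click", tiny_spec)
        a = simulate_epochs(trace, 10, 0.5, seed=7)
        b = simulate_epochs(trace, 10, 0.5, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_invalid_arguments_rejected(self, tiny_spec):
        subj = _subject(tiny_spec)
        trace = highpass_masked_trace(8.0, subj, "click", tiny_spec)
        with pytest.raises(ValueError):
            simulate_epochs(trace, 0, 0.5)
        with pytest.raises(ValueError):
            simulate_epochs(trace, 5, -1.0)


class TestCohort:
    def test_empty_cohort_is_allowed(self):
        data = simulate_cohort(SimCohortSpec(n_F=0, n_M=0, n_epochs=1))
        assert data.truth.empty and not data.epochs

    def test_cohort_is_deterministic_given_seed(self):
        spec = SimCohortSpec(n_F=1, n_M=1, n_epochs=3, epoch_noise_sd=0.3,
                             stimuli=(("click", "white"),), seed=5)
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        assert a.truth.equals(b.truth)
        key = next(iter(a.epochs))
        assert np.array_equal(a.epochs[key].data, b.epochs[key].data)

    def test_truth_table_covers_design(self, tiny_spec, tiny_cohort):
        truth = tiny_cohort.truth
        assert len(truth) == 4 * 1 * 2 * tiny_spec.n_bands
        assert set(truth.wave) == {"I", "V"}
        assert set(truth.f) == set(tiny_spec.band_freqs)

    def test_sex_specific_waveV_offset_applied(self):
        spec = SimCohortSpec(n_F=2, n_M=2, u_lat_sd=0.0,
                             sex_waveV_offset=0.4, n_epochs=1,
                             stimuli=(("click", "white"),))
        truth = simulate_latency_table(spec, lat_noise_sd=0.0)
        byx = truth.groupby(["wave", "sex"]).latency_ms.mean()
        assert byx["V", "M"] - byx["V", "F"] == pytest.approx(0.4)
        assert byx["I", "M"] - byx["I", "F"] == pytest.approx(0.0)

    def test_wave_and_sex_dispersion_can_differ(self):
        disp = {
            ("I", "F"): GroupDelayParams(K=4.0, D=0.4),
            ("I", "M"): GroupDelayParams(K=4.0, D=0.4),
            ("V", "F"): GroupDelayParams(K=5.0, D=0.5),
            ("V", "M"): GroupDelayParams(K=5.0, D=0.5),
        }
        spec = SimCohortSpec(n_F=1, n_M=1, dispersion=disp, u_lat_sd=0.0,
                             sex_waveV_offset=0.0, n_epochs=1,
                             stimuli=(("click", "white"),))
        subj = _subject(spec, u_lat=0.0)
        lat_I = true_latency(spec, "I", 1, "click", subj)
        lat_V = true_latency(spec, "V", 1, "click", subj)
        assert lat_I - spec.wave_templates["I"].base_latency == pytest.approx(4.0)
        assert lat_V - spec.wave_templates["V"].base_latency == pytest.approx(5.0)


def test_one_cycle_sine_peak_and_trough_positions():
    fs = 50_000.0
    t = np.arange(int(0.02 * fs)) / fs * 1e3
    y = one_cycle_sine(t, latency_ms=5.0, period_ms=2.0, amplitude=1.5)
    assert t[np.argmax(y)] == pytest.approx(5.0, abs=1e3 / fs)
    assert t[np.argmin(y)] == pytest.approx(6.0, abs=1e3 / fs)
    assert y.max() == pytest.approx(1.5, rel=1e-3)
    # support is one period wide
    assert np.all(y[t < 4.5 - 1e-9] == 0) and np.all(y[t > 6.5 + 1e-9] == 0)
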