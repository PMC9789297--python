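"""Synthetic derived-band ABR cohorts with known dispersion structure.

The generator emulates the statistical structure the derived-band
analysis assumes: each one-octave cochlear band contributes a unitary
wave-I and wave-V deflection (one-cycle sine), whose latency follows the
exponential dispersion law ``A_w + K * f**-D`` plus a per-subject random
intercept and a constant sex-specific wave-V offset.  Chirp stimuli
advance every band by the chirp's own group delay (perfect compensation
when the cohort's dispersion equals the chirp design constants) and may
attenuate high-band amplitudes to mimic chirp-induced desynchronization
of off-frequency responses.  Highpass masking at cutoff ``c`` removes
all bands above ``c``; single-trial epochs add white Gaussian noise.

Each band is assigned the frequency value used by the latency model:
its upper edge, with the open-ended top band one octave above its lower
edge (e.g. 16 kHz above an 8-kHz cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet, Waveform
from .dispersion import CE_CHIRP, GroupDelayParams, group_delay

__all__ = [
    "BROADBAND",
    "WaveTemplateParams",
    "SubjectParams",
    "SimCohortSpec",
    "CohortData",
    "band_upper_edges",
    "band_centre_labels",
    "one_cycle_sine",
    "band_response",
    "highpass_masked_trace",
    "simulate_epochs",
    "simulate_cohort",
    "simulate_latency_table",
]

BROADBAND = math.inf


@dataclass(frozen=True)
class WaveTemplateParams:
    """Unitary deflection of one ABR wave: a one-cycle sine.

    ``base_latency`` is the constant latency offset A_w (ms) added to the
    frequency-dependent group delay; ``width`` is the sine period (ms),
    wave V being wider and slower than wave I; ``amplitude`` is a global
    scale applied on top of the per-band amplitudes.
    """

    wave: str  # "I" | "V"
    base_latency: float
    width: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject random effects drawn by the cohort generator."""

    id: str
    sex: str  # "F" | "M"
    u_lat: float  # random latency intercept, ms
    u_amp: float  # multiplicative amplitude scalar, > 0
    sexV_offset: float  # constant wave-V latency offset for this subject's sex, ms

    def __post_init__(self) -> None:
        if self.u_amp <= 0:
            raise ValueError("u_amp must be positive")


def _default_wave_templates() -> dict:
    # wave V later, wider and larger than wave I
    return {
        "I": WaveTemplateParams(wave="I", base_latency=1.0, width=1.0),
        "V": WaveTemplateParams(wave="V", base_latency=4.5, width=2.0),
    }


def _default_band_amplitudes() -> dict:
    # per wave, lowest -> highest band; wave I weighted to basal bands
    return {
        "I": (0.10, 0.15, 0.25, 0.35, 0.40, 0.35),
        "V": (0.30, 0.40, 0.50, 0.60, 0.60, 0.45),
    }


@dataclass
class SimCohortSpec:
    """All generative parameters of a synthetic derived-band ABR study.

    Defaults mirror the acquisition conditions of the emulated paradigm:
    26 female / 18 male subjects, highpass-masking cutoffs 0.5-8 kHz in
    octave steps plus a broadband condition, 45-ms epochs (5-ms
    pre-stimulus baseline) at 16.384 kHz, 6000 sweeps per condition, and
    CE-chirp dispersion constants (K = 4.54 ms, D = 0.436) shared across
    waves and sexes (a null-true cohort).  ``dispersion`` may instead map
    ``(wave, sex)`` to distinct constants to impose dispersion effects.
    """

    n_F: int = 26
    n_M: int = 18
    cutoffs: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)  # kHz, strictly increasing
    dispersion: GroupDelayParams | dict = CE_CHIRP
    chirp_params: GroupDelayParams = CE_CHIRP
    wave_templates: dict = field(default_factory=_default_wave_templates)
    band_amplitudes: dict = field(default_factory=_default_band_amplitudes)
    offfreq_attenuation: tuple | None = None  # per-band chirp amplitude factor
    stimuli: tuple = (
        ("click", "white"),
        ("chirp", "white"),
        ("click", "pink"),
        ("chirp", "pink"),
    )
    u_lat_sd: float = 0.3  # between-subject latency SD, ms
    u_amp_sd: float = 0.3  # between-subject log-amplitude SD
    sex_waveV_offset: float = 0.2  # male-minus-female wave-V latency offset, ms
    epoch_noise_sd: float = 5.0  # single-trial additive noise SD (amplitude units)
    n_epochs: int = 6000
    fs: float = 16_384.0
    window_ms: tuple = (-5.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_F < 0 or self.n_M < 0:
            raise ValueError("subject counts must be >= 0")
        if self.epoch_noise_sd < 0:
            raise ValueError("epoch_noise_sd must be >= 0")
        cut = np.asarray(self.cutoffs, float)
        if cut.size < 1 or np.any(np.diff(cut) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
        for wave, amps in self.band_amplitudes.items():
            if len(amps) != self.n_bands:
                raise ValueError(
                    f"band_amplitudes[{wave!r}] must have {self.n_bands} entries"
                )
        if self.offfreq_attenuation is not None and len(
            self.offfreq_attenuation
        ) != self.n_bands:
            raise ValueError("offfreq_attenuation must have one entry per band")

    # -- band structure ------------------------------------------------
    @property
    def n_bands(self) -> int:
        return len(self.cutoffs) + 1

    @property
    def band_freqs(self) -> np.ndarray:
        """Model frequency of each band (upper edge; top band an octave up)."""
        return band_upper_edges(self.cutoffs)

    @property
    def band_labels(self) -> np.ndarray:
        return band_centre_labels(self.cutoffs)

    def dispersion_for(self, wave: str, sex: str) -> GroupDelayParams:
        if isinstance(self.dispersion, GroupDelayParams):
            return self.dispersion
        return self.dispersion[(wave, sex)]

    # -- time grid -----------------------------------------------------
    @property
    def times_ms(self) -> np.ndarray:
        n = int(round((self.window_ms[1] - self.window_ms[0]) * 1e-3 * self.fs))
        return self.window_ms[0] + np.arange(n) / self.fs * 1e3

    def draw_subjects(self, rng: np.random.Generator) -> list[SubjectParams]:
        subjects = []
        sexes = ["F"] * self.n_F + ["M"] * self.n_M
        for i, sex in enumerate(sexes):
            subjects.append(
                SubjectParams(
                    id=f"S{i:03d}",
                    sex=sex,
                    u_lat=float(rng.normal(0.0, self.u_lat_sd)),
                    u_amp=float(np.exp(rng.normal(0.0, self.u_amp_sd))),
                    sexV_offset=self.sex_waveV_offset if sex == "M" else 0.0,
                )
            )
        return subjects


def band_upper_edges(cutoffs) -> np.ndarray:
    """Frequency value of each derived band: its upper edge in kHz.

    The lowest band (below the first cutoff) has that cutoff as its
    upper edge; the open-ended top band is assigned one octave above its
    lower edge (twice the highest cutoff).
    """
    cut = np.asarray(cutoffs, float)
    return np.concatenate([cut, [2.0 * cut[-1]]])


def band_centre_labels(cutoffs) -> np.ndarray:
    """Octave-spaced centre-frequency labels (geometric mean of the band
    edges, rounded to one decimal); the edge bands are one octave wide by
    convention (e.g. cutoffs 0.5-8 kHz give 0.4, 0.7, 1.4, 2.8, 5.7, 11.3)."""
    cut = np.asarray(cutoffs, float)
    lowers = np.concatenate([[cut[0] / 2.0], cut])
    uppers = band_upper_edges(cutoffs)
    return np.round(np.sqrt(lowers * uppers), 1)


def one_cycle_sine(times_ms: np.ndarray, latency_ms: float, period_ms: float,
                   amplitude: float) -> np.ndarray:
    """One-cycle sine deflection peaking at ``latency_ms``.

    Support is ``[latency - T/4, latency + 3T/4]``; the positive peak
    sits at the latency and the trough half a period later.
    """
    t0 = latency_ms - period_ms / 4.0
    phase = (times_ms - t0) / period_ms
    inside = (phase >= 0.0) & (phase <= 1.0)
    out = np.zeros_like(times_ms, dtype=float)
    out[inside] = amplitude * np.sin(2 * np.pi * phase[inside])
    return out


def true_latency(spec: SimCohortSpec, wave: str, band_idx: int,
                 stimulus_kind: str, subj: SubjectParams) -> float:
    """Ground-truth peak latency of one band deflection, in ms."""
    f = spec.band_freqs[band_idx]
    tmpl = spec.wave_templates[wave]
    disp = spec.dispersion_for(wave, subj.sex)
    lat = tmpl.base_latency + group_delay(f, disp) + subj.u_lat
    if stimulus_kind == "chirp":
        lat -= group_delay(f, spec.chirp_params)
    if wave == "V":
        lat += subj.sexV_offset
    return float(lat)


def band_amplitude(spec: SimCohortSpec, wave: str, band_idx: int,
                   stimulus_kind: str, subj: SubjectParams) -> float:
    amp = spec.band_amplitudes[wave][band_idx] * spec.wave_templates[wave].amplitude
    amp *= subj.u_amp
    if stimulus_kind == "chirp" and spec.offfreq_attenuation is not None:
        amp *= spec.offfreq_attenuation[band_idx]
    return float(amp)


def band_response(wave: str, band_idx: int, stimulus_kind: str,
                  subj: SubjectParams, spec: SimCohortSpec) -> Waveform:
    """Noise-free unitary deflection of one wave in one derived band."""
    if not 0 <= band_idx < spec.n_bands:
        raise ValueError(f"band index {band_idx} outside 0..{spec.n_bands - 1}")
    t = spec.times_ms
    lat = true_latency(spec, wave, band_idx, stimulus_kind, subj)
    amp = band_amplitude(spec, wave, band_idx, stimulus_kind, subj)
    x = one_cycle_sine(t, lat, spec.wave_templates[wave].width, amp)
    return Waveform(fs=spec.fs, samples=x, t0=spec.window_ms[0] * 1e-3,
                    meta={"wave": wave, "band": band_idx,
                          "stimulus": stimulus_kind, "subject": subj.id})


def highpass_masked_trace(cutoff: float, subj: SubjectParams,
                          stimulus_kind: str, spec: SimCohortSpec) -> Waveform:
    """Noise-free response under highpass masking at ``cutoff`` (kHz).

    Sums both waves over all bands whose upper edge does not exceed the
    cutoff; ``cutoff=inf`` gives the unmasked broadband response.
    """
    if not (cutoff == BROADBAND or any(np.isclose(cutoff, c) for c in spec.cutoffs)):
        raise ValueError(f"cutoff {cutoff} kHz is not a masking condition")
    t = spec.times_ms
    x = np.zeros_like(t)
    for b in range(spec.n_bands):
        if spec.band_freqs[b] <= cutoff + 1e-12:
            for wave in spec.wave_templates:
                lat = true_latency(spec, wave, b, stimulus_kind, subj)
                amp = band_amplitude(spec, wave, b, stimulus_kind, subj)
                x += one_cycle_sine(t, lat, spec.wave_templates[wave].width, amp)
    return Waveform(fs=spec.fs, samples=x, t0=spec.window_ms[0] * 1e-3,
                    meta={"cutoff": cutoff, "stimulus": stimulus_kind,
                          "subject": subj.id})


def simulate_epochs(trace: Waveform, n_epochs: int, noise_sd: float,
                    seed: int | np.random.Generator = 0) -> EpochSet:
    """Replicate a trace into noisy single-trial epochs.

    Adds independent white Gaussian noise per sample and trial and tags
    alternating stimulus polarity (the deflection itself does not depend
    on polarity; the tag is bookkeeping for averaging conventions).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    data = np.tile(trace.samples, (n_epochs, 1))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return EpochSet(fs=trace.fs, data=data, t0=trace.t0,
                    meta=dict(trace.meta))


@dataclass
class CohortData:
    """Simulated cohort: epoched recordings plus the ground-truth table.

    ``epochs`` maps ``(subject_id, stimulus_kind, profile, cutoff)`` to an
    EpochSet (cutoff in kHz, ``math.inf`` for broadband).  ``truth`` is a
    long-format latency/amplitude table with one row per subject x wave x
    band x stimulus x profile.
    """

    spec: SimCohortSpec
    subjects: list
    epochs: dict
    truth: pd.DataFrame

    def conditions(self):
        return sorted({(k[1], k[2]) for k in self.epochs})


def _truth_rows(spec: SimCohortSpec, subjects) -> pd.DataFrame:
    rows = []
    labels = spec.band_labels
    freqs = spec.band_freqs
    for subj in subjects:
        for kind, profile in spec.stimuli:
            for wave in spec.wave_templates:
                for b in range(spec.n_bands):
                    rows.append(
                        {
                            "subject": subj.id,
                            "sex": subj.sex,
                            "wave": wave,
                            "stimulus": kind,
                            "profile": profile,
                            "band": labels[b],
                            "f": freqs[b],
                            "latency_ms": true_latency(spec, wave, b, kind, subj),
                            "amplitude": band_amplitude(spec, wave, b, kind, subj),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_cohort(spec: SimCohortSpec) -> CohortData:
    """Simulate the full study: every subject x stimulus x masking condition.

    Deterministic given ``spec.seed``.  Returns epoched recordings and
    the ground-truth latency table used by recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = spec.draw_subjects(rng)
    truth = _truth_rows(spec, subjects)
    conditions = list(spec.cutoffs) + [BROADBAND]
    epochs = {}
    for subj in subjects:
        for kind, profile in spec.stimuli:
            for cutoff in conditions:
                trace = highpass_masked_trace(cutoff, subj, kind, spec)
                child = rng.spawn(1)[0]
                es = simulate_epochs(trace, spec.n_epochs, spec.epoch_noise_sd,
                                     seed=child)
                es.meta.update({"profile": profile, "sex": subj.sex})
                epochs[(subj.id, kind, profile, cutoff)] = es
    return CohortData(spec=spec, subjects=subjects, epochs=epochs, truth=truth)


def simulate_latency_table(spec: SimCohortSpec, lat_noise_sd: float = 0.1,
                           seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a latency table directly from the generative model.

    Adds per-observation Gaussian measurement noise (``lat_noise_sd`` ms)
    to the ground-truth latencies, bypassing waveform synthesis; used for
    model-recovery studies where only the latency level matters.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subjects = spec.draw_subjects(rng)
    table = _truth_rows(spec, subjects)
    table["latency_ms"] = table["latency_ms"] + rng.normal(
        0.0, lat_noise_sd, size=len(table)
    )
    return table
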