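"""Click/chirp stimulus synthesis and highpass masking noise.

Stimuli are built by summing sinusoids on a regular frequency grid
(default: integer multiples of 10 Hz between 0.25 and 8 kHz).  A click
aligns all components in cosine phase at a reference time; a chirp
time-advances each component by the cochlear group delay ``t_g(f)`` so
that low-frequency components, whose travelling-wave delay is longest,
are presented first.  Because the two constructions differ only in
component phase, a click and chirp with the same spectral profile have
identical magnitude spectra and identical overall energy.

Spectral profiles: "white" (flat energy density) or "pink" (energy
density proportional to 1/f).  Spectral edges are rounded with
quarter-sine/-cosine ramps one auditory-filter bandwidth (ERB_N) wide to
avoid audible edge tones.

Masking noise for the highpass-masking (derived-band) paradigm is
constructed directly in the discrete frequency domain with an ideal
(brick-wall) highpass edge, which makes the buffer cyclically
continuable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .containers import Waveform
from .dispersion import GroupDelayParams, erb_width, group_delay

__all__ = [
    "StimulusSpec",
    "component_grid",
    "component_amplitudes",
    "synthesize",
    "masking_noise",
    "write_wav",
    "read_wav",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Specification of a click or chirp stimulus.

    Frequencies are in kHz except ``component_spacing`` and ``fs`` (Hz).
    ``edge_ramp`` optionally overrides the (low, high) spectral ramp
    widths in Hz; by default each ramp is one ERB_N at the band edge.
    """

    kind: str = "click"  # click | chirp
    profile: str = "white"  # white | pink
    f_lo: float = 0.25
    f_hi: float = 8.0
    component_spacing: float = 10.0
    fs: float = 50_000.0
    edge_ramp: tuple[float, float] | None = None
    t_ref: float = 0.010  # reference (click peak) time, s
    duration: float | None = None  # default: one grid period, 1/spacing
    normalize: bool = True  # scale to unit energy, keep scale in meta
    phase_mode: str = "group-delay"  # group-delay | component-delay

    def __post_init__(self) -> None:
        if self.kind not in ("click", "chirp"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.phase_mode not in ("group-delay", "component-delay"):
            raise ValueError(f"unknown phase mode {self.phase_mode!r}")
        if self.profile not in ("white", "pink"):
            raise ValueError(f"unknown spectral profile {self.profile!r}")
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be below f_hi")
        if self.component_spacing <= 0:
            raise ValueError("component_spacing must be positive")

    @property
    def ramp_widths(self) -> tuple[float, float]:
        if self.edge_ramp is not None:
            return self.edge_ramp
        return (erb_width(self.f_lo), erb_width(self.f_hi))


def component_grid(spec: StimulusSpec) -> np.ndarray:
    """Component frequencies in Hz: multiples of the spacing within band."""
    sp = spec.component_spacing
    lo_hz, hi_hz = spec.f_lo * 1e3, spec.f_hi * 1e3
    k_lo = int(np.ceil(lo_hz / sp - 1e-9))
    k_hi = int(np.floor(hi_hz / sp + 1e-9))
    if k_lo < 1:
        k_lo = 1
    return np.arange(k_lo, k_hi + 1) * sp


def component_amplitudes(spec: StimulusSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """Component amplitudes implementing the spectral profile and edge ramps.

    Energy density of component amplitude a is a**2, so the pink (1/f)
    profile uses a proportional to f**-1/2.  The low edge rises as a
    quarter sine over the low ramp width; the high edge falls as a
    quarter cosine over the high ramp width.
    """
    f = np.asarray(freqs_hz, dtype=float)
    if spec.profile == "white":
        amp = np.ones_like(f)
    else:  # pink: energy density ~ 1/f, referenced to the low band edge
        amp = np.sqrt(spec.f_lo * 1e3 / f)
    w_lo, w_hi = spec.ramp_widths
    lo_hz, hi_hz = spec.f_lo * 1e3, spec.f_hi * 1e3
    ramp = np.ones_like(f)
    rising = f < lo_hz + w_lo
    ramp[rising] = np.sin(0.5 * np.pi * (f[rising] - lo_hz) / w_lo)
    falling = f > hi_hz - w_hi
    ramp[falling] = np.cos(0.5 * np.pi * (f[falling] - (hi_hz - w_hi)) / w_hi)
    return amp * np.clip(ramp, 0.0, 1.0)


def synthesize(spec: StimulusSpec, p: GroupDelayParams | None = None) -> Waveform:
    """Synthesize a click or chirp stimulus as a sum of sinusoids.

    Parameters
    ----------
    spec : StimulusSpec
    p : GroupDelayParams, optional
        Group-delay law for chirp construction; ignored for clicks and
        required for chirps.  The chirp's energy at frequency ``f`` is
        advanced by ``t_g(f)`` relative to the click reference so that a
        matched cochlea (same law) responds synchronously.

    Notes
    -----
    Two phase constructions are available.  The default
    (``phase_mode="group-delay"``) integrates the prescribed delay law
    into the component phases, so the stimulus's stationary-phase group
    delay -- the time at which a narrowband slice around ``f`` actually
    peaks -- equals ``-t_g(f)`` relative to the click.  The literal
    per-component construction (``"component-delay"``), which shifts the
    sinusoid at ``f`` by ``t_g(f)``, yields a measured group delay of
    ``(1 - D) * t_g(f)`` for a power-law ``t_g`` (since
    ``d(f * t_g)/df = (1 - D) t_g``), i.e. a chirp that undercompensates
    the very dispersion it encodes; it is provided for comparison.

    Returns
    -------
    Waveform
        With ``meta`` recording kind, profile, dispersion constants, the
        raw (pre-normalization) energy and the applied scale factor.
    """
    if spec.fs <= 2 * spec.f_hi * 1e3:
        raise ValueError(
            f"fs={spec.fs} Hz aliases the {spec.f_hi} kHz band edge"
        )
    if spec.kind == "chirp":
        if p is None:
            raise ValueError("chirp synthesis requires GroupDelayParams")
    else:
        p = GroupDelayParams(K=0.0, D=0.0)

    freqs = component_grid(spec)
    amps = component_amplitudes(spec, freqs)
    duration = spec.duration if spec.duration is not None else 1.0 / spec.component_spacing
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs

    f_khz = freqs / 1e3
    t_ref_ms = spec.t_ref * 1e3
    if spec.phase_mode == "component-delay":
        # literal per-component time advance by t_g(f)
        phi = 2 * np.pi * f_khz * (group_delay(f_khz, p) - t_ref_ms)
    else:
        # phase integral of the prescribed group delay: the narrowband
        # energy at f peaks at t_ref - t_g(f).  For t_g = A + K f^-D,
        # integral of t_g df = A f + K f^(1-D)/(1-D)  (K ln f if D = 1).
        if abs(p.D - 1.0) < 1e-12:
            integral = p.A * f_khz + p.K * np.log(f_khz)
        else:
            integral = p.A * f_khz + p.K * f_khz ** (1.0 - p.D) / (1.0 - p.D)
        phi = 2 * np.pi * (integral - f_khz * t_ref_ms)
    # time grid in ms so f_khz * t_ms counts cycles directly
    phase = 2 * np.pi * f_khz[None, :] * (t[:, None] * 1e3) + phi[None, :]
    x = (np.cos(phase) * amps[None, :]).sum(axis=1)

    raw_energy = float(np.sum(x**2) / spec.fs)
    scale = 1.0
    if spec.normalize and raw_energy > 0:
        scale = 1.0 / np.sqrt(raw_energy)
        x = x * scale
    meta = {
        "kind": spec.kind,
        "profile": spec.profile,
        "K": p.K,
        "D": p.D,
        "A": p.A,
        "f_lo_khz": spec.f_lo,
        "f_hi_khz": spec.f_hi,
        "raw_energy": raw_energy,
        "scale": scale,
    }
    return Waveform(fs=spec.fs, samples=x, t0=0.0, meta=meta)


def masking_noise(
    profile: str,
    cutoff: float,
    duration: float = 10.5,
    fs: float = 50_000.0,
    seed: int | np.random.Generator = 0,
    rms: float = 1.0,
) -> Waveform:
    """Highpass masking noise with an ideal (brick-wall) spectral edge.

    The buffer is built in the discrete frequency domain (deterministic
    magnitude envelope matching the stimulus profile, uniform random
    phases), so it is endpoint-periodic and can be played cyclically.

    Parameters
    ----------
    profile : {"white", "pink"}
    cutoff : float
        Highpass cutoff in kHz; must lie in (0, fs/2).
    duration : float
        Buffer length in seconds (default 10.5).
    seed : int or Generator
        Phase randomization source; two seeds share the same magnitude
        envelope but have different sample paths.
    rms : float
        Target root-mean-square amplitude of the buffer.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    cutoff_hz = cutoff * 1e3
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    if profile not in ("white", "pink"):
        raise ValueError(f"unknown spectral profile {profile!r}")
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.zeros_like(freqs)
    band = freqs >= cutoff_hz
    if profile == "white":
        mag[band] = 1.0
    else:
        mag[band] = np.sqrt(cutoff_hz / freqs[band])
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = mag * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = mag[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    x_rms = np.sqrt(np.mean(x**2))
    if x_rms > 0:
        x = x * (rms / x_rms)
    return Waveform(
        fs=fs,
        samples=x,
        t0=0.0,
        meta={"profile": profile, "cutoff_khz": cutoff, "seed": str(seed)},
    )


def write_wav(path: str | Path, wf: Waveform) -> None:
    """Write a Waveform as float32 WAV with a JSON metadata sidecar."""
    path = Path(path)
    wavfile.write(path, int(round(wf.fs)), wf.samples.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"fs": wf.fs, "t0": wf.t0, **wf.meta}, indent=1))


def read_wav(path: str | Path) -> Waveform:
    path = Path(path)
    fs, data = wavfile.read(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Waveform(fs=float(meta.get("fs", fs)), samples=np.asarray(data, float),
                    t0=float(meta.get("t0", 0.0)), meta=meta)
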