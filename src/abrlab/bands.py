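"""Derived-band algebra and stacked ABR construction.

Derived bands isolate the response contribution of one-octave cochlear
regions by subtracting averaged responses obtained under highpass
masking with successive cutoffs; by construction the bands telescope
back to the broadband response exactly.  Stacked ABRs undo cross-band
latency dispersion by time-shifting every band to a common latency
reference before summing, mimicking an ideally tailored chirp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .containers import AverageResponse, Waveform
from .preprocess import cross_splice
from .simulate import band_centre_labels, band_upper_edges

__all__ = [
    "HighpassMaskedSet",
    "DerivedBand",
    "DerivedBandSet",
    "StackedResponse",
    "derive_bands",
    "time_shift",
    "stack",
    "stack_spliced",
    "effective_mean",
]


@dataclass
class HighpassMaskedSet:
    """Per-condition averaged responses keyed by highpass cutoff (kHz),
    plus the unmasked broadband response.  All responses share one grid."""

    masked: dict  # cutoff kHz -> AverageResponse, strictly increasing keys
    broadband: AverageResponse
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cuts = self.cutoffs
        if len(cuts) < 1:
            raise ValueError("at least one masked condition required")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        for resp in self.masked.values():
            if not resp.same_grid(self.broadband):
                raise ValueError("all responses must share the time grid")

    @property
    def cutoffs(self) -> list:
        return sorted(self.masked)


@dataclass
class DerivedBand:
    lower_edge: float  # kHz
    upper_edge: float  # kHz (inf for the top band)
    centre_label: float  # kHz, printed band name
    response: AverageResponse


@dataclass
class DerivedBandSet:
    """Ordered one-octave band responses, lowest to highest frequency."""

    bands: list
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, i) -> DerivedBand:
        return self.bands[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.centre_label for b in self.bands])

    def responses(self) -> list:
        return [b.response for b in self.bands]

    def band_sum(self) -> AverageResponse:
        total = np.sum([b.response.values for b in self.bands], axis=0)
        ref = self.bands[0].response
        return AverageResponse(fs=ref.fs, values=total, t0=ref.t0,
                               meta={"derived": "band_sum"})


@dataclass
class StackedResponse:
    """A stacked ABR plus the stacking provenance."""

    response: AverageResponse
    mode: str = "average"  # average | sex | individual
    wave: str = "V"  # I | V | spliced
    reference_ms: float = float("nan")
    latencies: dict = field(default_factory=dict)


def derive_bands(h: HighpassMaskedSet) -> DerivedBandSet:
    """Subtract successive highpass-masked responses into derived bands.

    The lowest band is the response at the lowest cutoff itself; interior
    bands are differences of neighbouring cutoffs; the top band is
    broadband minus the highest cutoff.  Bands are labelled by the
    geometric mean of their edges (edge bands one octave wide), so the
    sum over bands telescopes to the broadband response exactly.
    """
    cuts = h.cutoffs
    labels = band_centre_labels(cuts)
    uppers = band_upper_edges(cuts)
    lowers = np.concatenate([[cuts[0] / 2.0], cuts])
    bands = []
    for j in range(len(cuts) + 1):
        if j == 0:
            values = h.masked[cuts[0]].values.copy()
            lo, up = 0.0, uppers[0]
        elif j < len(cuts):
            values = h.masked[cuts[j]].values - h.masked[cuts[j - 1]].values
            lo, up = lowers[j], uppers[j]
        else:
            values = h.broadband.values - h.masked[cuts[-1]].values
            lo, up = lowers[j], math.inf
        ref = h.broadband
        resp = AverageResponse(fs=ref.fs, values=values, t0=ref.t0,
                               meta={**h.meta, "band": labels[j]})
        bands.append(DerivedBand(lower_edge=lo, upper_edge=up,
                                 centre_label=float(labels[j]), response=resp))
    return DerivedBandSet(bands=bands, meta=dict(h.meta))


def time_shift(resp: AverageResponse, shift_ms: float,
               mode: str = "sinc") -> AverageResponse:
    """Shift a response later by ``shift_ms`` (negative = earlier).

    ``sinc`` applies a band-limited (FFT phase) shift on a zero-padded
    copy to avoid circular wrap-around; ``nearest`` rolls by the nearest
    whole number of samples.
    """
    n = resp.n
    if mode == "nearest":
        k = int(round(shift_ms * 1e-3 * resp.fs))
        out = np.zeros(n)
        if k >= 0:
            out[k:] = resp.values[: n - k] if k < n else 0.0
        else:
            out[:k] = resp.values[-k:]
        return resp.copy(values=out)
    if mode != "sinc":
        raise ValueError(f"unknown shift mode {mode!r}")
    pad = n  # zero-pad by a full window to keep wrapped energy out
    npad = n + 2 * pad
    buf = np.zeros(npad)
    buf[pad:pad + n] = resp.values
    f = np.fft.rfftfreq(npad, d=1.0 / resp.fs)
    spec = np.fft.rfft(buf) * np.exp(-2j * np.pi * f * shift_ms * 1e-3)
    out = np.fft.irfft(spec, n=npad)[pad:pad + n]
    return resp.copy(values=out)


def stack(bands: DerivedBandSet, latencies, reference: float | None = None,
          mode: str = "average", shift_mode: str = "sinc") -> StackedResponse:
    """Align derived bands to a common latency reference and sum.

    Parameters
    ----------
    bands : DerivedBandSet
    latencies : mapping or sequence
        Per-band latency in ms (keyed by centre label, or ordered like
        the bands).  Each band is shifted by ``reference - latency``.
    reference : float, optional
        Alignment latency in ms; defaults to the across-band mean of the
        supplied latencies, so the stack stays in its natural time range.
    """
    labels = bands.labels
    if isinstance(latencies, dict):
        try:
            lats = np.array([float(latencies[lb]) for lb in labels])
        except KeyError as e:
            raise ValueError(f"missing latency for band {e.args[0]}") from e
    else:
        lats = np.asarray(latencies, float)
        if lats.size != len(bands):
            raise ValueError("one latency per band required")
    if np.any(~np.isfinite(lats)):
        raise ValueError("latencies must be finite")
    ref = float(np.mean(lats)) if reference is None else float(reference)
    shifted = [
        time_shift(b.response, ref - lat, mode=shift_mode)
        for b, lat in zip(bands, lats)
    ]
    total = np.sum([s.values for s in shifted], axis=0)
    out = AverageResponse(fs=shifted[0].fs, values=total, t0=shifted[0].t0,
                          meta={**bands.meta, "stacked": mode})
    return StackedResponse(response=out, mode=mode, reference_ms=ref,
                           latencies=dict(zip(labels, lats)))


def stack_spliced(bands: DerivedBandSet, lat_waveI, lat_waveV,
                  reference: float | None = None, mode: str = "average",
                  shift_mode: str = "sinc") -> StackedResponse:
    """Stack separately on wave-I and wave-V latencies, then cross-splice.

    The early (<= 4 ms) segment carries the wave-I-aligned stack, the
    late (>= 6 ms) segment the wave-V-aligned stack, with the standard
    2-ms linear crossfade centred on 5 ms.
    """
    sI = stack(bands, lat_waveI, reference=reference, mode=mode,
               shift_mode=shift_mode)
    sV = stack(bands, lat_waveV, reference=reference, mode=mode,
               shift_mode=shift_mode)
    spliced = cross_splice(sV.response, sI.response)
    return StackedResponse(response=spliced, mode=mode, wave="spliced",
                           reference_ms=sI.reference_ms,
                           latencies={"I": sI.latencies, "V": sV.latencies})


def effective_mean(responses) -> AverageResponse:
    """Pointwise mean divided by pointwise across-response SD.

    A dimensionless SNR-like trace: compensating inter-individual latency
    variability (individual stacking) raises it even when the raw mean
    amplitude gain is modest.  Samples with zero SD are emitted as 0 and
    flagged in ``meta['zero_sd_mask']``.
    """
    resps = [r.response if isinstance(r, StackedResponse) else r for r in responses]
    if len(resps) < 2:
        raise ValueError("effective_mean needs at least two responses")
    for r in resps[1:]:
        if not r.same_grid(resps[0]):
            raise ValueError("responses must share the time grid")
    data = np.array([r.values for r in resps])
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    mask = sd == 0
    out = np.zeros_like(mean)
    out[~mask] = mean[~mask] / sd[~mask]
    return AverageResponse(fs=resps[0].fs, values=out, t0=resps[0].t0,
                           meta={"effective_mean": True,
                                 "zero_sd_mask": mask})
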