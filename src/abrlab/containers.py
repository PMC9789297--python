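"""In-memory containers for uniformly sampled evoked-response data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Waveform", "EpochSet", "AverageResponse"]


@dataclass
class Waveform:
    """A single uniformly sampled real-valued trace.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    samples : ndarray
        Sample values.
    t0 : float
        Time of sample 0 in seconds (negative for pre-stimulus baselines).
    """

    fs: float
    samples: np.ndarray
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1e3

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def energy(self) -> float:
        """Sum of squared samples divided by fs (integral of x**2 dt)."""
        return float(np.sum(self.samples**2) / self.fs)

    def copy(self, **changes: Any) -> "Waveform":
        wf = replace(self, **changes)
        wf.samples = np.array(wf.samples, dtype=float)
        return wf


@dataclass
class EpochSet:
    """Epoched single-trial recordings: a trial x sample matrix.

    The time window must contain 0 (stimulus onset); ``t0`` is the time of
    the first sample in seconds.  ``polarity`` records the alternating
    stimulus polarity tag per trial (+1/-1).
    """

    fs: float
    data: np.ndarray
    t0: float
    polarity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.t0 > 0:
            raise ValueError("epoch window must contain time 0")
        if self.polarity is None:
            self.polarity = np.where(np.arange(self.n_trials) % 2 == 0, 1, -1)
        else:
            self.polarity = np.asarray(self.polarity, dtype=int)
            if self.polarity.size != self.n_trials:
                raise ValueError("polarity labels must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1e3


@dataclass
class AverageResponse:
    """A per-condition average evoked response on a uniform time grid.

    ``hp_variant`` records which highpass filtering branch produced the
    trace (100, 150, or "spliced"); ``meta`` carries condition labels
    (subject, stimulus kind, spectral profile, masking cutoff, ...).
    """

    fs: float
    values: np.ndarray
    t0: float
    hp_variant: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AverageResponse values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AverageResponse values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1e3

    def same_grid(self, other: "AverageResponse", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and np.isclose(self.fs, other.fs, rtol=rtol)
            and np.isclose(self.t0, other.t0, rtol=rtol, atol=1e-12)
        )

    def copy(self, **changes: Any) -> "AverageResponse":
        resp = replace(self, meta=dict(self.meta), **changes)
        resp.values = np.array(resp.values, dtype=float)
        return resp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "value": self.values})
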