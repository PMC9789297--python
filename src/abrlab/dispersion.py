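"""Cochlear dispersion (group-delay) law and auditory-filter bandwidths.

The travelling wave in the cochlea reaches apical (low-frequency) places
later than basal (high-frequency) ones.  Across a wide range of evoked
response data this frequency-dependent delay is well captured by a
two-parameter power law

    t_g(f) = K * f**(-D)        [t_g in ms, f in kHz]

which is also the group-delay function used to construct
dispersion-compensating (CE-style) chirp stimuli.  The same law, plus a
constant offset ``A`` for neural conduction, is the fixed-effect mean of
the latency mixed model in :mod:`abrlab.model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GroupDelayParams", "CE_CHIRP", "group_delay", "erb_width"]


@dataclass(frozen=True)
class GroupDelayParams:
    """Constants of the exponential group-delay law ``A + K * f**-D``.

    Parameters
    ----------
    K : float
        Group delay at 1 kHz, in milliseconds.  Must be >= 0.
    D : float
        Dimensionless decay exponent.  Must be >= 0.
    A : float, optional
        Constant latency offset in milliseconds (0 for stimulus design;
        nonzero when the law models neural response latencies).
    """

    K: float
    D: float
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")

    def __call__(self, f):
        return group_delay(f, self)


#: Constants of the standard wave-V-optimised chirp (K = 4.54 ms, D = 0.436),
#: derived from click-evoked derived-band latencies.
CE_CHIRP = GroupDelayParams(K=4.54, D=0.436)


def group_delay(f, p: GroupDelayParams):
    """Evaluate the group-delay law at frequency ``f``.

    Parameters
    ----------
    f : float or array_like
        Frequency in kHz; must be strictly positive.
    p : GroupDelayParams

    Returns
    -------
    float or ndarray
        ``p.A + p.K * f**(-p.D)`` in milliseconds.  Scalar in, scalar out.
    """
    farr = np.asarray(f, dtype=float)
    if np.any(farr <= 0):
        raise ValueError("frequency must be strictly positive (kHz)")
    out = p.A + p.K * farr ** (-p.D)
    return float(out) if np.isscalar(f) or farr.ndim == 0 else out


def erb_width(f):
    """Equivalent rectangular bandwidth of the normal auditory filter, in Hz.

    Uses the standard Glasberg–Moore convention
    ``ERB_N(f) = 24.7 * (4.37 * f_kHz + 1)``.

    Parameters
    ----------
    f : float or array_like
        Centre frequency in kHz; must be strictly positive.
    """
    farr = np.asarray(f, dtype=float)
    if np.any(farr <= 0):
        raise ValueError("frequency must be strictly positive (kHz)")
    out = 24.7 * (4.37 * farr + 1.0)
    return float(out) if np.isscalar(f) or farr.ndim == 0 else out
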