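"""Non-linear curve registration (dynamic time warping) of ABR waveforms.

Individual evoked responses differ mainly in the timing, not the shape,
of their deflections.  Plain cross-sectional averaging therefore blurs
peaks.  Registration estimates, per response, a smooth monotone time
warp toward a common target under a penalized squared difference of the
derivatives (PSDD) criterion, iterating between warping and updating
the target with the mean of the warped responses ("average-target"
scheme).  The converged target is the *structural average*; waves are
picked once on it, and individual latencies are recovered by mapping
the picked times back through each response's inverse warp.

Warps are monotone piecewise-linear maps with a small number of
interior knots, fixed to the identity at the window endpoints; ABR
features are few and smooth, so a coarse parameterization regularizes
the problem and keeps the inverse trivially computable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import gaussian_filter1d

from .containers import AverageResponse

__all__ = [
    "WarpFunction",
    "WavePick",
    "PickSet",
    "RegistrationResult",
    "register",
    "pick_peaks",
    "individual_latencies",
    "align_pair",
]

_MIN_SLOPE = 0.05  # lower bound on warp derivative (dimensionless)


@dataclass
class WarpFunction:
    """Monotone piecewise-linear warp between individual and target time.

    Stored as knot pairs ``(t_target, t_individual)``; the map is the
    identity outside the registration window.  Following the convention
    that the warp maps *individual* time to *target* time, ``__call__``
    is the forward map and :meth:`to_individual` the inverse used to
    carry picked target-time latencies back to a subject.
    """

    knots_target: np.ndarray
    knots_individual: np.ndarray

    def __post_init__(self) -> None:
        self.knots_target = np.asarray(self.knots_target, float)
        self.knots_individual = np.asarray(self.knots_individual, float)
        if self.knots_target.shape != self.knots_individual.shape:
            raise ValueError("knot arrays must have equal length")
        if np.any(np.diff(self.knots_target) <= 0) or np.any(
            np.diff(self.knots_individual) <= 0
        ):
            raise ValueError("warp knots must be strictly increasing")

    def to_target(self, t_individual):
        return np.interp(t_individual, self.knots_individual, self.knots_target)

    def to_individual(self, t_target):
        if np.any(np.asarray(t_target) < self.knots_target[0] - 1e-9) or np.any(
            np.asarray(t_target) > self.knots_target[-1] + 1e-9
        ):
            raise ValueError("time outside the registered window")
        return np.interp(t_target, self.knots_target, self.knots_individual)

    __call__ = to_target

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.knots_target, self.knots_individual))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_target_ms": self.knots_target,
                             "t_individual_ms": self.knots_individual})


@dataclass
class WavePick:
    wave: str
    peak_ms: float = float("nan")
    trough_ms: float = float("nan")
    peak_amp: float = float("nan")
    trough_amp: float = float("nan")
    missing: bool = False


@dataclass
class PickSet:
    picks: dict  # wave -> WavePick

    def __getitem__(self, wave: str) -> WavePick:
        return self.picks[wave]

    def __iter__(self):
        return iter(self.picks.values())


@dataclass
class RegistrationResult:
    warps: list
    structural_average: AverageResponse
    target_window_ms: tuple
    converged: bool
    n_iter: int
    snr_flags: np.ndarray
    meta: dict = field(default_factory=dict)


def _warp_grid(d: np.ndarray, knot_t: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Individual time u(t) on the grid from interior-knot offsets d."""
    offsets = np.concatenate([[0.0], d, [0.0]])
    return grid + np.interp(grid, knot_t, offsets)


def _objective(d, knot_t, grid, x, dtarget, lam, norm, dt):
    u = _warp_grid(d, knot_t, grid)
    du = np.diff(u) / dt
    barrier = np.sum(np.square(np.minimum(du - _MIN_SLOPE, 0.0))) * 1e6
    y = np.interp(u, grid, x)
    dy = np.gradient(y, dt)
    misfit = np.mean((dy - dtarget) ** 2) / norm
    rough = np.mean((du - 1.0) ** 2)
    return misfit + lam * rough + barrier


def register(responses, initial_target: AverageResponse | None = None,
             penalty: float = 0.05, n_knots: int = 10, max_iter: int = 10,
             tol: float = 1e-3, window_ms: tuple | None = (0.0, 12.0),
             smooth_ms: float = 1.0,
             snr_flag_threshold: float = 1.0) -> RegistrationResult:
    """Register responses to an evolving average target (``at`` + PSDD).

    Parameters
    ----------
    responses : sequence of AverageResponse
        At least two responses on a common grid.
    initial_target : AverageResponse, optional
        Default: the cross-sectional average of the inputs (for masked
        broadband registration, pass the broadband cross-sectional
        average explicitly).
    penalty : float
        Roughness weight lambda on the mean squared deviation of the
        warp slope from 1; the derivative misfit is normalized by the
        target's mean squared derivative so lambda is scale-free.
    n_knots : int
        Interior knots of the piecewise-linear warps within the window.
    window_ms : tuple
        Registration window (default 0-12 ms, the ABR range); warps are
        the identity outside it.
    smooth_ms : float
        Initial Gaussian smoothing SD (ms) for a coarse-to-fine
        schedule: the derivative misfit is evaluated on progressively
        less smoothed copies (halving each iteration), which lets large
        latency offsets escape the local minima of the raw criterion.
        The structural average itself is always built from raw data.
    snr_flag_threshold : float
        Responses whose post-registration residual power exceeds this
        fraction of the target power are flagged as too noisy for the
        warp to be trusted.

    Returns
    -------
    RegistrationResult
        Per-response warps, the structural average on the full grid, and
        convergence/SNR diagnostics.
    """
    resps = list(responses)
    if len(resps) < 2:
        raise ValueError("registration needs at least two responses")
    ref = resps[0]
    for r in resps[1:]:
        if not r.same_grid(ref):
            raise ValueError("responses must share the time grid")
    t_all = ref.times_ms
    if window_ms is None:
        window_ms = (float(t_all[0]), float(t_all[-1]))
    sel = (t_all >= window_ms[0]) & (t_all <= window_ms[1])
    grid = t_all[sel]
    dt = 1e3 / ref.fs
    knot_t = np.linspace(grid[0], grid[-1], n_knots + 2)

    data = np.array([r.values[sel] for r in resps])
    if initial_target is None:
        target = data.mean(axis=0)
    else:
        if not initial_target.same_grid(ref):
            raise ValueError("initial target must share the time grid")
        target = initial_target.values[sel].copy()

    n = len(resps)
    d_all = np.zeros((n, n_knots))
    warped = data.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sigma = smooth_ms / 2.0 ** (it - 1)
        sigma_samp = sigma / dt
        if sigma_samp > 0.25:
            target_s = gaussian_filter1d(target, sigma_samp)
            data_s = gaussian_filter1d(data, sigma_samp, axis=-1)
        else:
            target_s, data_s = target, data
        dtarget = np.gradient(target_s, dt)
        norm = float(np.mean(dtarget**2)) + 1e-30
        for i in range(n):
            res = optimize.minimize(
                _objective, d_all[i],
                args=(knot_t, grid, data_s[i], dtarget, penalty, norm, dt),
                method="L-BFGS-B", options={"maxiter": 60},
            )
            d_all[i] = res.x
            u = _warp_grid(d_all[i], knot_t, grid)
            warped[i] = np.interp(u, grid, data[i])
        new_target = warped.mean(axis=0)
        scale = float(np.sqrt(np.mean(target**2))) + 1e-30
        delta = float(np.sqrt(np.mean((new_target - target) ** 2))) / scale
        target = new_target
        if delta < tol and sigma_samp <= 0.25:
            # only declare convergence once the schedule has reached raw data
            converged = True
            break
    if not converged:
        warnings.warn("registration did not converge; returning best iterate",
                      stacklevel=2)

    # package warps with guaranteed monotone knots
    warps = []
    for i in range(n):
        u_knots = knot_t + np.concatenate([[0.0], d_all[i], [0.0]])
        u_knots = _enforce_monotone(u_knots)
        warps.append(WarpFunction(knots_target=knot_t, knots_individual=u_knots))

    structural = ref.copy(values=_embed(ref, sel, target))
    structural.meta = {"structural_average": True, "window_ms": window_ms}
    tgt_power = float(np.mean(target**2)) + 1e-30
    snr_flags = np.array([
        float(np.mean((warped[i] - target) ** 2)) / tgt_power > snr_flag_threshold
        for i in range(n)
    ])
    return RegistrationResult(warps=warps, structural_average=structural,
                              target_window_ms=window_ms, converged=converged,
                              n_iter=it, snr_flags=snr_flags,
                              meta={"penalty": penalty, "n_knots": n_knots})


def _enforce_monotone(u: np.ndarray, min_step: float = 1e-6) -> np.ndarray:
    out = u.copy()
    for k in range(1, out.size):
        if out[k] <= out[k - 1] + min_step:
            out[k] = out[k - 1] + min_step
    return out


def _embed(ref: AverageResponse, sel: np.ndarray, window_values: np.ndarray):
    values = ref.values.copy()
    values[sel] = window_values
    return values


def pick_peaks(structural: AverageResponse, wave_windows: dict) -> PickSet:
    """Pick each wave's peak and subsequent trough on the structural average.

    ``wave_windows`` maps wave name to a broad (lo, hi) search window in
    ms.  The peak is the largest interior local maximum in the window
    (earliest on ties); the trough is the deepest subsequent interior
    local minimum before the window's end.  A window with no local
    extremum yields a flagged missing pick rather than a boundary value.
    """
    t = structural.times_ms
    x = structural.values
    picks = {}
    for wave, (lo, hi) in wave_windows.items():
        idx = np.flatnonzero((t >= lo) & (t <= hi))
        if idx.size < 3:
            picks[wave] = WavePick(wave=wave, missing=True)
            continue
        interior = idx[1:-1]
        is_max = (x[interior] >= x[interior - 1]) & (x[interior] > x[interior + 1])
        maxima = interior[is_max]
        if maxima.size == 0:
            picks[wave] = WavePick(wave=wave, missing=True)
            continue
        peak = maxima[np.argmax(x[maxima])]  # argmax returns earliest on ties
        after = interior[(interior > peak)]
        is_min = (x[after] <= x[after - 1]) & (x[after] < x[after + 1])
        minima = after[is_min]
        if minima.size == 0:
            picks[wave] = WavePick(wave=wave, peak_ms=float(t[peak]),
                                   peak_amp=float(x[peak]), missing=True)
            continue
        trough = minima[np.argmin(x[minima])]
        picks[wave] = WavePick(wave=wave, peak_ms=float(t[peak]),
                               trough_ms=float(t[trough]),
                               peak_amp=float(x[peak]),
                               trough_amp=float(x[trough]))
    return PickSet(picks=picks)


def individual_latencies(warps, picks: PickSet, ids=None,
                         meta: dict | None = None) -> pd.DataFrame:
    """Map structural-average picks back to individual latencies.

    latency_subject = warp_subject^-1(pick time); rows are one per
    response x wave, in long format ready for the latency table.
    """
    if ids is None:
        ids = [f"R{i:03d}" for i in range(len(warps))]
    rows = []
    for rid, warp in zip(ids, warps):
        for pick in picks:
            if pick.missing and np.isnan(pick.peak_ms):
                continue
            row = {"subject": rid, "wave": pick.wave,
                   "latency_ms": float(warp.to_individual(pick.peak_ms))}
            if not np.isnan(pick.trough_ms):
                row["trough_ms"] = float(warp.to_individual(pick.trough_ms))
            if meta:
                row.update(meta)
            rows.append(row)
    return pd.DataFrame(rows)


def align_pair(a: AverageResponse, b: AverageResponse, **kwargs):
    """Warp two waveforms to their joint mean target before comparison.

    Returns the pair of aligned responses; amplitudes are preserved up
    to the time reparameterization, which prevents latency differences
    from masquerading as amplitude differences in pointwise tests.
    """
    joint = a.copy(values=(a.values + b.values) / 2.0)
    result = register([a, b], initial_target=joint, **kwargs)
    sel = (a.times_ms >= result.target_window_ms[0]) & (
        a.times_ms <= result.target_window_ms[1]
    )
    grid = a.times_ms[sel]
    out = []
    for resp, warp in zip((a, b), result.warps):
        u = warp.to_individual(grid)
        warped = resp.copy()
        vals = warped.values.copy()
        vals[sel] = np.interp(u, grid, resp.values[sel])
        warped.values = vals
        warped.meta = dict(resp.meta)
        warped.meta["aligned"] = True
        out.append(warped)
    return out[0], out[1]
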