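"""Statistical machinery around the dispersion model.

Model comparison follows the dual-reporting convention: a frequentist
chi-squared likelihood-ratio test alongside a BIC-based Bayes factor
(exp of half the BIC difference), reported in whichever direction
exceeds 1.  Waveform-level comparisons use one-sample t_max permutation
tests with sign flipping for family-wise error control; amplitude
summaries integrate pointwise absolute values over wave time windows;
uncertainty on cohort summaries comes from subject-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AverageResponse
from .model import LatencyDispersionModel, LatencyDispersionResults

__all__ = [
    "TestResult",
    "adjust_chirp_latencies",
    "fit_dispersion",
    "compare_models",
    "power_two_sample",
    "tmax_permutation",
    "aggregate_amplitude",
    "chirp_benefit",
    "bootstrap_se",
    "heteroscedastic_reweight",
]


@dataclass
class TestResult:
    """Outcome of a model comparison or waveform permutation test."""

    statistic: float = float("nan")
    df: int = 0
    pvalue: float = float("nan")
    bf: float = float("nan")  # Bayes factor value, always >= 1
    bf_direction: str = ""  # "BF01" (null) or "BF10" (alternative)
    t_scores: np.ndarray | None = None
    significant: np.ndarray | None = None
    times_ms: np.ndarray | None = None
    critical_value: float = float("nan")
    meta: dict = field(default_factory=dict)

    def bf_label(self, cap: float = 150.0) -> str:
        """Formatted Bayes factor with the conventional '> 150' cap."""
        if self.bf > cap:
            return f"{self.bf_direction} > {cap:g}"
        return f"{self.bf_direction} = {self.bf:.3g}"


def adjust_chirp_latencies(table: pd.DataFrame) -> pd.DataFrame:
    """Shift chirp-evoked latencies by the grand click-chirp difference.

    Adds the average click-minus-chirp latency difference (across all
    subjects, waves, bands and spectral profiles) to every chirp row, so
    click- and chirp-evoked latencies can share one group-delay function
    in the dispersion model.  Click rows are untouched.
    """
    kinds = set(table["stimulus"].unique())
    if not {"click", "chirp"} <= kinds:
        raise ValueError("table must contain both click and chirp rows")
    keys = [c for c in ("subject", "sex", "wave", "profile", "band", "f")
            if c in table.columns]
    wide = table.pivot_table(index=keys, columns="stimulus",
                             values="latency_ms")
    paired = wide.dropna(subset=["click", "chirp"])
    if len(paired):
        delta = float((paired["click"] - paired["chirp"]).mean())
    else:  # no matched pairs: fall back to difference of grand means
        delta = float(
            table.loc[table.stimulus == "click", "latency_ms"].mean()
            - table.loc[table.stimulus == "chirp", "latency_ms"].mean()
        )
    out = table.copy()
    out.loc[out.stimulus == "chirp", "latency_ms"] += delta
    out.attrs["chirp_adjustment_ms"] = delta
    return out


def fit_dispersion(table: pd.DataFrame, strata: dict | None = None,
                   random_intercept: bool = True, weights=None,
                   **fit_kwargs) -> LatencyDispersionResults:
    """Convenience wrapper: build and fit a LatencyDispersionModel."""
    model = LatencyDispersionModel(table, strata=strata,
                                   random_intercept=random_intercept,
                                   weights=weights)
    return model.fit(**fit_kwargs)


def compare_models(fit_null: LatencyDispersionResults,
                   fit_alt: LatencyDispersionResults) -> TestResult:
    """Likelihood-ratio test plus BIC Bayes factor for nested ML fits.

    chi2 = 2 * (logLik_alt - logLik_null) on df = extra parameters;
    BF01 = exp((BIC_alt - BIC_null) / 2), reported in the direction in
    which the evidence exceeds 1.
    """
    if fit_null.nobs != fit_alt.nobs:
        raise ValueError("models must be fitted to the same data")
    names_null = set(fit_null.model.param_names)
    names_alt = set(fit_alt.model.param_names)
    if not names_null <= names_alt:
        raise ValueError("models are not nested")
    df = fit_alt.k_params - fit_null.k_params
    chi2 = 2.0 * (fit_alt.llf - fit_null.llf)
    if df == 0:
        p = 1.0 if chi2 <= 0 else float(sps.chi2.sf(chi2, 1))
    else:
        p = float(sps.chi2.sf(max(chi2, 0.0), df))
    bf01 = float(np.exp((fit_alt.bic - fit_null.bic) / 2.0))
    if bf01 >= 1.0:
        bf, direction = bf01, "BF01"
    else:
        bf, direction = 1.0 / bf01, "BF10"
    return TestResult(statistic=float(chi2), df=df, pvalue=p, bf=bf,
                      bf_direction=direction)


def power_two_sample(diff: float, sd: float, n1: int, n2: int,
                     alpha: float = 0.05, two_sided: bool = True,
                     method: str = "noncentral-t") -> float:
    """Power of the two-sample t-test for a standardized mean difference.

    The effect size is ``d = diff / sd``.  The default evaluates the
    exact noncentral-t distribution with noncentrality
    ``d * sqrt(n1*n2/(n1+n2))`` on ``n1+n2-2`` df; ``method="normal"``
    uses the large-sample normal approximation, which for these designs
    runs 1-2 percentage points higher.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    d = diff / sd
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    df = n1 + n2 - 2
    a = alpha / 2 if two_sided else alpha
    if method == "noncentral-t":
        tcrit = sps.t.ppf(1 - a, df)
        power = sps.nct.sf(tcrit, df, ncp)
        if two_sided:
            power += sps.nct.cdf(-tcrit, df, ncp)
    elif method == "normal":
        zcrit = sps.norm.ppf(1 - a)
        power = sps.norm.cdf(ncp - zcrit)
        if two_sided:
            power += sps.norm.cdf(-ncp - zcrit)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(power)


def tmax_permutation(differences, n_perm: int = 5000, alpha: float = 0.05,
                     window_ms: tuple | None = (0.0, 12.0), fs: float | None = None,
                     t0: float = 0.0, seed: int | np.random.Generator = 0) -> TestResult:
    """Pointwise one-sample t_max permutation test with sign flipping.

    Parameters
    ----------
    differences : ndarray (subjects x time) or list of AverageResponse
        Per-subject paired waveform differences.
    window_ms : tuple, optional
        Time window to test (requires a time axis: pass
        AverageResponses, or ``fs``/``t0`` for a bare matrix); ``None``
        tests every column.

    Notes
    -----
    The null distribution is built from random sign flips of whole
    subjects; family-wise error is controlled by referring each
    pointwise ``|t|`` to the permutation distribution of the maximum
    ``|t|`` over the window.  Zero-variance time points get t = 0.
    """
    if isinstance(differences, (list, tuple)) and isinstance(
            differences[0], AverageResponse):
        fs = differences[0].fs
        t0 = differences[0].t0
        data = np.array([r.values for r in differences])
    else:
        data = np.atleast_2d(np.asarray(differences, float))
    n_subj, n_time = data.shape
    if n_subj < 2:
        raise ValueError("t_max test needs at least two subjects")
    times_ms = (t0 + np.arange(n_time) / fs) * 1e3 if fs else np.arange(
        n_time, dtype=float)
    if window_ms is not None:
        sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
        data = data[:, sel]
        times_ms = times_ms[sel]
        n_time = data.shape[1]

    rng = np.random.default_rng(seed)

    def tstat(signed_sums: np.ndarray) -> np.ndarray:
        # sum of squares is invariant under sign flips
        mean = signed_sums / n_subj
        var = (ss - signed_sums**2 / n_subj) / (n_subj - 1)
        out = np.zeros_like(mean)
        ok = var > 0
        out[ok] = mean[ok] / np.sqrt(var[ok] / n_subj)
        return out

    ss = (data**2).sum(axis=0)
    t_obs = tstat(data.sum(axis=0))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    perm_sums = signs @ data
    t_perm = np.abs(tstat(perm_sums))
    max_t = t_perm.max(axis=1)
    crit = float(np.quantile(max_t, 1 - alpha))
    # permutation p-value per point against the max-|t| distribution
    pvals = (1 + (max_t[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (
        n_perm + 1)
    significant = pvals <= alpha
    return TestResult(statistic=float(np.max(np.abs(t_obs))),
                      df=n_subj - 1,
                      pvalue=float(pvals.min()),
                      t_scores=t_obs, significant=significant,
                      times_ms=times_ms, critical_value=crit,
                      meta={"n_perm": n_perm, "alpha": alpha})


def aggregate_amplitude(response: AverageResponse, window_ms: tuple) -> float:
    """Integrated absolute amplitude over a wave window, in amplitude*ms.

    The standard windows are 2-5 ms (wave I), 5-9 ms (wave V) and
    2-9 ms (both); the integral is trapezoidal on the native grid.
    """
    t = response.times_ms
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    if sel.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    return float(np.trapezoid(np.abs(response.values[sel]), t[sel]))


def chirp_benefit(agg_click: float, agg_chirp: float) -> float:
    """Chirp-minus-click aggregate amplitude as a percent of click."""
    if agg_click <= 0:
        raise ValueError("click aggregate amplitude must be positive")
    return 100.0 * (agg_chirp - agg_click) / agg_click


def bootstrap_se(values, statistic=np.mean, n_boot: int = 5000,
                 seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Subject-level bootstrap mean and standard error of a statistic.

    Resamples subjects with replacement ``n_boot`` times; returns the
    mean of the statistic over resamples and its standard deviation
    (the bootstrap SE).
    """
    values = np.asarray(values)
    n = values.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least two subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    stats_ = np.array([statistic(values[row], axis=0)
                       if _takes_axis(statistic) else statistic(values[row])
                       for row in idx], dtype=float)
    return float(stats_.mean()), float(stats_.std(ddof=1))


def _takes_axis(statistic) -> bool:
    return statistic in (np.mean, np.median, np.std, np.sum)


def heteroscedastic_reweight(table: pd.DataFrame, factor: str,
                             value_col: str = "latency_ms",
                             alpha: float = 0.05,
                             center: str = "median"):
    """Levene test across factor levels; inverse-variance weights if unequal.

    Returns ``(weights, TestResult)``.  If the Levene test is not
    significant at ``alpha`` (or the factor has a single level) the
    weights are all 1; otherwise each observation receives a weight
    proportional to the inverse of its level's variance, normalized to
    mean 1, ready for :class:`~abrlab.model.LatencyDispersionModel`.
    """
    levels = table[factor].unique()
    n = len(table)
    if len(levels) < 2:
        return np.ones(n), TestResult(statistic=float("nan"), pvalue=1.0,
                                      meta={"levels": 1})
    groups = [table.loc[table[factor] == lv, value_col].to_numpy()
              for lv in levels]
    stat, p = sps.levene(*groups, center=center)
    weights = np.ones(n)
    if p < alpha:
        variances = {lv: float(np.var(g, ddof=1)) for lv, g in zip(levels, groups)}
        w = np.array([1.0 / variances[lv] for lv in table[factor]])
        weights = w * (n / w.sum())
    return weights, TestResult(statistic=float(stat), df=len(levels) - 1,
                               pvalue=float(p),
                               meta={"weighted": bool(p < alpha)})
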