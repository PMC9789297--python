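"""Nonlinear mixed-effects model for derived-band ABR latencies.

Each observed latency (subject x wave x band x stimulus x profile) is
modelled as a constant offset plus the exponential cochlear-dispersion
law, with a random intercept per subject:

    latency_ij = A_j + K_j * f_ij**(-D_j) + b_i + e_ij
    b_i ~ N(0, tau**2),   e_ij ~ N(0, sigma**2 / w_ij)

where ``f`` is the band frequency in kHz (band upper edge; 16 kHz for
the open-ended top band) and the stratum index ``j`` says which of
``A``, ``K`` and ``D`` vary with which two-level factors (wave, sex,
stimulus, spectral profile).  Factors are effect-coded (+1/2, -1/2), so
the intercepts are cross-stratum means and the factor coefficients are
the contrasts (e.g. ``K_wave = K_I - K_V``).

Estimation is by maximum likelihood on the marginal Gaussian
likelihood, profiled per subject through the rank-one structure of the
random intercept, with multi-start quasi-Newton optimization (the
dispersion surface is mildly nonconvex in ``(K, D)``).  Standard errors
come from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LatencyDispersionModel", "LatencyDispersionResults"]

#: canonical level order per factor; the contrast is first minus second
_LEVELS = {
    "wave": ("I", "V"),
    "sex": ("F", "M"),
    "stimulus": ("click", "chirp"),
    "profile": ("white", "pink"),
}


def _code_factor(values: pd.Series, factor: str) -> np.ndarray:
    levels = _LEVELS.get(factor)
    if levels is None:
        levels = tuple(sorted(values.unique()))
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly two levels")
    seen = set(values.unique())
    if not seen <= set(levels):
        raise ValueError(f"unexpected levels {seen - set(levels)} in {factor!r}")
    return np.where(values.to_numpy() == levels[0], 0.5, -0.5)


def _design(table: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(table))]
    names = ["const"]
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(table))
        for p in parts:
            if p not in table.columns:
                raise ValueError(f"factor column {p!r} not in table")
            col = col * _code_factor(table[p], p)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


class LatencyDispersionModel:
    """Exponential-dispersion latency model with subject random intercepts.

    Parameters
    ----------
    table : DataFrame
        Long-format latency table with columns ``subject``,
        ``latency_ms``, ``f`` (band frequency, kHz) and any factor
        columns referenced by ``strata``.
    strata : dict, optional
        Maps each of ``"A"``, ``"K"``, ``"D"`` to the factor terms it
        varies by (e.g. ``{"A": ["wave", "sex", "wave:sex"],
        "K": ["wave", "sex"], "D": ["wave", "sex"]}``).  Omitted
        parameters are shared across all observations.  The null model
        of the dispersion analysis lets only ``A`` vary.
    random_intercept : bool
        Include the per-subject random intercept (default True).
    weights : array_like, optional
        Per-observation precision weights (residual variance is
        ``sigma**2 / w``), e.g. from inverse-variance reweighting after
        a heteroscedasticity test.
    """

    def __init__(self, table: pd.DataFrame, strata: dict | None = None,
                 random_intercept: bool = True, weights=None):
        required = {"subject", "latency_ms", "f"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table is missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        strata = dict(strata or {})
        for key in strata:
            if key not in ("A", "K", "D"):
                raise ValueError(f"unknown stratified parameter {key!r}")
        self.strata = {k: list(strata.get(k, [])) for k in ("A", "K", "D")}
        self.random_intercept = bool(random_intercept)

        self.y = self.table["latency_ms"].to_numpy(float)
        self.f = self.table["f"].to_numpy(float)
        if np.any(self.f <= 0):
            raise ValueError("band frequencies must be positive (kHz)")
        self.log_f = np.log(self.f)
        if weights is None:
            self.weights = np.ones_like(self.y)
        else:
            self.weights = np.asarray(weights, float)
            if self.weights.shape != self.y.shape or np.any(self.weights <= 0):
                raise ValueError("weights must be positive, one per row")

        self.Xa, na = _design(self.table, self.strata["A"])
        self.Xk, nk = _design(self.table, self.strata["K"])
        self.Xd, nd = _design(self.table, self.strata["D"])
        self.param_names = (
            [f"A[{n}]" for n in na] + [f"K[{n}]" for n in nk]
            + [f"D[{n}]" for n in nd]
        )
        if self.random_intercept:
            self.param_names.append("log_re_sd")
        self.param_names.append("log_resid_sd")
        self._slices = {
            "A": slice(0, self.Xa.shape[1]),
            "K": slice(self.Xa.shape[1], self.Xa.shape[1] + self.Xk.shape[1]),
            "D": slice(self.Xa.shape[1] + self.Xk.shape[1],
                       self.Xa.shape[1] + self.Xk.shape[1] + self.Xd.shape[1]),
        }
        # group observations by subject for the profiled likelihood
        codes, _ = pd.factorize(self.table["subject"], sort=True)
        order = np.argsort(codes, kind="stable")
        self._order = order
        self._group_sizes = np.bincount(codes)
        self._n_groups = self._group_sizes.size

    # -- likelihood ----------------------------------------------------
    @property
    def k_params(self) -> int:
        return len(self.param_names)

    @property
    def nobs(self) -> int:
        return self.y.size

    def _mean(self, params: np.ndarray) -> np.ndarray:
        a = self.Xa @ params[self._slices["A"]]
        k = self.Xk @ params[self._slices["K"]]
        d = self.Xd @ params[self._slices["D"]]
        return a + k * np.exp(-np.clip(d, -20, 20) * self.log_f)

    def loglike(self, params: np.ndarray) -> float:
        params = np.asarray(params, float)
        # keep variance components in a numerically sane range; the
        # optimizer may probe extreme log-SDs
        params = params.copy()
        params[-1] = np.clip(params[-1], -15.0, 10.0)
        if self.random_intercept:
            params[-2] = np.clip(params[-2], -15.0, 10.0)
        r = (self.y - self._mean(params))[self._order]
        w = self.weights[self._order]
        sigma2 = np.exp(2.0 * params[-1])
        dv = sigma2 / w  # per-observation residual variance
        if self.random_intercept:
            tau2 = np.exp(2.0 * params[-2])
        else:
            tau2 = 0.0
        ll = -0.5 * self.nobs * np.log(2 * np.pi)
        start = 0
        for n_i in self._group_sizes:
            ri = r[start:start + n_i]
            di = dv[start:start + n_i]
            inv_d = 1.0 / di
            s = inv_d.sum()
            u = float(ri @ inv_d)  # 1' D^-1 r
            quad = float(ri @ (ri * inv_d))
            logdet = float(np.log(di).sum())
            if tau2 > 0:
                denom = 1.0 + tau2 * s
                quad -= tau2 * u * u / denom
                logdet += np.log(denom)
            ll += -0.5 * (logdet + quad)
            start += n_i
        return float(ll)

    def _nll(self, params):
        ll = self.loglike(params)
        return 1e12 if not np.isfinite(ll) else -ll

    def _start_params(self) -> np.ndarray:
        K0, D0 = 4.54, 0.436
        base_a = float(np.mean(self.y - K0 * self.f ** (-D0)))
        start = np.zeros(self.k_params)
        start[self._slices["A"].start] = base_a
        start[self._slices["K"].start] = K0
        start[self._slices["D"].start] = D0
        resid_sd = max(float(np.std(self.y - self._mean(start))), 1e-3)
        if self.random_intercept:
            start[-2] = np.log(max(resid_sd / np.sqrt(2), 1e-3))
        start[-1] = np.log(max(resid_sd / np.sqrt(2), 1e-3))
        return start

    def fit(self, start_params=None, n_restarts: int = 3,
            maxiter: int = 500) -> "LatencyDispersionResults":
        """Maximize the marginal likelihood with multi-start L-BFGS.

        Starts at the canonical chirp constants (K = 4.54, D = 0.436)
        plus deterministic perturbations; the best converged optimum is
        kept.  Non-convergence of every start is flagged on the result
        rather than raised.
        """
        base = self._start_params() if start_params is None else np.asarray(
            start_params, float)
        rng = np.random.default_rng(12345)
        starts = [base]
        for _ in range(n_restarts):
            pert = base.copy()
            pert += rng.normal(0.0, 0.1, size=base.size)
            starts.append(pert)
        best = None
        any_converged = False
        for s in starts:
            res = optimize.minimize(self._nll, s, method="L-BFGS-B",
                                    options={"maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
            any_converged = any_converged or bool(res.success)
        if not any_converged:
            warnings.warn("dispersion model fit did not converge",
                          stacklevel=2)
        cov = self._cov_params(best.x)
        return LatencyDispersionResults(self, best.x, cov,
                                        converged=any_converged)

    def _cov_params(self, params: np.ndarray) -> np.ndarray:
        hess = _numerical_hessian(self._nll, params)
        try:
            cov = np.linalg.inv(hess)
            if np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        return cov

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "LatencyDispersionModel":
        return cls(table, **kwargs)


def _numerical_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            if i == j:
                # xpp/xmm carry a double step along axis i when i == j
                hess[i, i] = (fun(xpp) - 2.0 * f0 + fun(xmm)) / ((2 * h[i]) ** 2)
            else:
                hess[i, j] = hess[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4 * h[i] * h[j])
    return hess


@dataclass
class LatencyDispersionResults:
    """Fitted dispersion NLMM: estimates, uncertainty and criteria."""

    model: LatencyDispersionModel
    _params: np.ndarray
    cov: np.ndarray
    converged: bool = True

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov), 0, None)),
                         index=self.model.param_names)

    @property
    def llf(self) -> float:
        return self.model.loglike(self._params)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def re_sd(self) -> float:
        if not self.model.random_intercept:
            return 0.0
        return float(np.exp(self.params["log_re_sd"]))

    @property
    def resid_sd(self) -> float:
        return float(np.exp(self.params["log_resid_sd"]))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self._params - z * self.bse.to_numpy()
        hi = self._params + z * self.bse.to_numpy()
        return pd.DataFrame({"lower": lo, "upper": hi},
                            index=self.model.param_names)

    def fittedvalues(self) -> np.ndarray:
        return self.model._mean(self._params)

    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues()

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        sub = LatencyDispersionModel(
            table.assign(latency_ms=0.0)
            if "latency_ms" not in table.columns else table,
            strata=self.model.strata,
            random_intercept=False,
        )
        # reuse fixed-effect block of the parameter vector
        k_fixed = sub.Xa.shape[1] + sub.Xk.shape[1] + sub.Xd.shape[1]
        return sub._mean(np.concatenate([self._params[:k_fixed], [0.0]]))

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Latency dispersion mixed model (ML)",
            "=" * 64,
            f"observations: {self.nobs}   subjects: {self.model._n_groups}"
            f"   params: {self.k_params}",
            f"logLik: {self.llf:.3f}   AIC: {self.aic:.2f}   BIC: {self.bic:.2f}",
            f"random-intercept SD: {self.re_sd:.4f} ms   "
            f"residual SD: {self.resid_sd:.4f} ms",
            "-" * 64,
            f"{'parameter':<18}{'estimate':>10}{'se':>10}{'[0.025':>12}{'0.975]':>10}",
        ]
        for name in self.model.param_names:
            est = self.params[name]
            se = self.bse[name]
            lines.append(
                f"{name:<18}{est:>10.4f}{se:>10.4f}"
                f"{ci.loc[name, 'lower']:>12.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)
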