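"""Bivariate dynamic-conditional-correlation pre-test.

Standard two-stage Gaussian quasi-maximum-likelihood: a GARCH(1,1) fit per
margin, then a DCC(1,1) recursion on the standardized residuals,

    Q_t = (1 - a - b) S + a e_{t-1} e_{t-1}' + b Q_{t-1},
    rho_t = Q_{12,t} / sqrt(Q_{11,t} Q_{22,t}),

with (a, b) estimated by constrained QMLE.  The resulting correlation path
is the model-based evidence for (or against) a time-varying relation
between the growth series and a health indicator, run before committing to
the time-varying-parameter model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["GarchFit", "DccResult", "Garch11", "DCC", "fit_garch11", "fit_dcc",
           "dynamic_correlation"]

_STATIONARITY_BOUND = 0.999
# fixed multi-start grid for the quasi-Newton searches
_GARCH_STARTS = [(0.05, 0.90), (0.10, 0.80), (0.02, 0.95), (0.20, 0.60), (0.10, 0.50)]
_DCC_STARTS = [(0.05, 0.90), (0.10, 0.80), (0.02, 0.85), (0.20, 0.50), (0.01, 0.30)]


@dataclass
class GarchFit:
    """Fitted GARCH(1,1): variance equation h_t = omega + alpha r_{t-1}^2
    + beta h_{t-1} with alpha + beta < 1."""

    omega: float
    alpha: float
    beta: float
    conditional_sd_path: np.ndarray
    loglik: float


@dataclass
class DccResult:
    """Fitted DCC(1,1): correlation dynamics (a, b) with a + b < 1 and the
    conditional correlation path rho_t in [-1, 1]."""

    a: float
    b: float
    rho_path: np.ndarray
    unconditional_corr: float
    loglik: float
    garch_fits: tuple[GarchFit, GarchFit] | None = None


def _garch_variance_path(r: np.ndarray, omega: float, alpha: float, beta: float) -> np.ndarray:
    """Conditional variance recursion, h_0 = sample variance."""
    T = len(r)
    h0 = float(np.var(r))
    drive = omega + alpha * r[:-1] ** 2
    h = np.empty(T)
    h[0] = h0
    if T > 1:
        h[1:], _ = lfilter([1.0], [1.0, -beta], drive, zi=[beta * h0])
    return h


def _garch_negloglik(params: np.ndarray, r: np.ndarray) -> float:
    omega, alpha, beta = params
    if omega <= 0 or alpha < 0 or beta < 0:
        return 1e10
    if alpha + beta >= _STATIONARITY_BOUND:
        return 1e8 * (1.0 + alpha + beta)
    h = _garch_variance_path(r, omega, alpha, beta)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        return 1e10
    return 0.5 * float(np.sum(np.log(2.0 * np.pi * h) + r**2 / h))


class Garch11(BaseEstimator):
    """Gaussian QMLE of a GARCH(1,1) with the stationarity constraint
    alpha + beta < 1, by bounded quasi-Newton search from a fixed grid of
    starting points.

    Attributes after fit: ``omega_``, ``alpha_``, ``beta_``,
    ``conditional_sd_`` (T,), ``loglik_``, ``std_residuals_``.
    """

    def __init__(self, demean: bool = True, min_obs: int = 50):
        self.demean = demean
        self.min_obs = min_obs

    def fit(self, y, X=None) -> "Garch11":
        r = np.asarray(y, dtype=float).ravel()
        if len(r) < self.min_obs:
            raise ValueError(f"need at least {self.min_obs} observations, got {len(r)}")
        if np.var(r) == 0.0:
            raise ValueError("constant series: GARCH likelihood is degenerate")
        if self.demean:
            r = r - r.mean()
        var = float(np.var(r))

        best = None
        for alpha0, beta0 in _GARCH_STARTS:
            x0 = np.array([max(var * (1.0 - alpha0 - beta0), 1e-8), alpha0, beta0])
            res = minimize(
                _garch_negloglik,
                x0,
                args=(r,),
                method="L-BFGS-B",
                bounds=[(1e-10, 10.0 * var), (0.0, 0.999), (0.0, 0.999)],
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("GARCH optimization failed from every start")
        omega, alpha, beta = best.x
        if alpha + beta >= _STATIONARITY_BOUND:  # pragma: no cover - penalty keeps interior
            warnings.warn("GARCH estimate at stationarity boundary; constrained to interior")
            scale = (_STATIONARITY_BOUND - 1e-4) / (alpha + beta)
            alpha, beta = alpha * scale, beta * scale
        h = _garch_variance_path(r, omega, alpha, beta)
        self.omega_, self.alpha_, self.beta_ = float(omega), float(alpha), float(beta)
        self.conditional_sd_ = np.sqrt(h)
        self.loglik_ = -_garch_negloglik(np.array([omega, alpha, beta]), r)
        self.std_residuals_ = r / self.conditional_sd_
        return self

    def to_result(self) -> GarchFit:
        check_is_fitted(self, "omega_")
        return GarchFit(self.omega_, self.alpha_, self.beta_, self.conditional_sd_, self.loglik_)


def _dcc_rho_path(E: np.ndarray, a: float, b: float, S: np.ndarray) -> np.ndarray:
    """Correlation path from the DCC recursion, Q_1 = S."""
    T = len(E)
    rho = np.empty(T)
    Q = S.copy()
    rho[0] = Q[0, 1] / np.sqrt(Q[0, 0] * Q[1, 1])
    for t in range(1, T):
        e = E[t - 1]
        Q = (1.0 - a - b) * S + a * np.outer(e, e) + b * Q
        rho[t] = Q[0, 1] / np.sqrt(Q[0, 0] * Q[1, 1])
    return rho


def _dcc_negloglik(params: np.ndarray, E: np.ndarray, S: np.ndarray) -> float:
    a, b = params
    if a < 0 or b < 0:
        return 1e10
    if a + b >= _STATIONARITY_BOUND:
        return 1e8 * (1.0 + a + b)
    rho = _dcc_rho_path(E, a, b, S)
    rho = np.clip(rho, -0.9999, 0.9999)
    e1, e2 = E[:, 0], E[:, 1]
    det = 1.0 - rho**2
    quad = (e1**2 - 2.0 * rho * e1 * e2 + e2**2) / det
    return 0.5 * float(np.sum(np.log(det) + quad - (e1**2 + e2**2)))


class DCC(BaseEstimator):
    """DCC(1,1) correlation stage on a pair of standardized residuals.

    ``fit(E)`` with E of shape (T, 2); attributes ``a_``, ``b_``,
    ``rho_path_``, ``unconditional_corr_``, ``loglik_``.  ``constant=True``
    pins a = b = 0 so the path collapses to the sample correlation.
    """

    def __init__(self, constant: bool = False):
        self.constant = constant

    def fit(self, E, y=None) -> "DCC":
        E = np.asarray(E, dtype=float)
        if E.ndim != 2 or E.shape[1] != 2:
            raise ValueError("E must have shape (T, 2)")
        T = len(E)
        if T < 20:
            raise ValueError("need at least 20 observations for the DCC stage")
        S = np.corrcoef(E.T)
        if not np.all(np.isfinite(S)):
            raise ValueError("degenerate residual pair")

        if self.constant:
            a, b = 0.0, 0.0
        else:
            best = None
            for a0, b0 in _DCC_STARTS:
                res = minimize(
                    _dcc_negloglik,
                    np.array([a0, b0]),
                    args=(E, S),
                    method="L-BFGS-B",
                    bounds=[(0.0, 0.999), (0.0, 0.999)],
                )
                if best is None or res.fun < best.fun:
                    best = res
            a, b = best.x
            if a + b >= _STATIONARITY_BOUND:
                warnings.warn("DCC estimate at stationarity boundary; constrained to interior")
                scale = (_STATIONARITY_BOUND - 1e-4) / (a + b)
                a, b = a * scale, b * scale
        self.a_, self.b_ = float(a), float(b)
        self.S_ = S
        self.rho_path_ = _dcc_rho_path(E, self.a_, self.b_, S)
        self.unconditional_corr_ = float(S[0, 1])
        self.loglik_ = -_dcc_negloglik(np.array([self.a_, self.b_]), E, S)
        return self

    def to_result(self, garch_fits: tuple[GarchFit, GarchFit] | None = None) -> DccResult:
        check_is_fitted(self, "a_")
        return DccResult(
            a=self.a_,
            b=self.b_,
            rho_path=self.rho_path_,
            unconditional_corr=self.unconditional_corr_,
            loglik=self.loglik_,
            garch_fits=garch_fits,
        )


def fit_garch11(series: np.ndarray) -> GarchFit:
    """QMLE GARCH(1,1) fit of a (demeaned) return series."""
    return Garch11().fit(series).to_result()


def fit_dcc(std_residual_pair: np.ndarray) -> DccResult:
    """DCC(1,1) correlation stage on standardized residuals (T, 2)."""
    E = np.asarray(std_residual_pair, dtype=float)
    if E.ndim != 2 or E.shape[1] != 2:
        raise ValueError("std_residual_pair must have shape (T, 2)")
    return DCC().fit(E).to_result()


def dynamic_correlation(growth: np.ndarray, health_indicator: np.ndarray) -> DccResult:
    """Full two-stage pipeline: demean, GARCH(1,1) per series, standardize,
    DCC(1,1) on the residual pair."""
    g = np.asarray(growth, dtype=float).ravel()
    h = np.asarray(health_indicator, dtype=float).ravel()
    if len(g) != len(h):
        raise ValueError("series must have equal length")
    fit_g = Garch11().fit(g)
    fit_h = Garch11().fit(h)
    E = np.column_stack([fit_g.std_residuals_, fit_h.std_residuals_])
    dcc = DCC().fit(E)
    return dcc.to_result(garch_fits=(fit_g.to_result(), fit_h.to_result()))
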