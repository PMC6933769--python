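"""Forgetting-factor Kalman filter/smoother for the TVP-FAVAR.

The model couples an observation equation with time-varying loadings,

    x_{i,t} = z_t' lambda_{i,t} + v_{i,t},        v_{i,t} ~ N(0, V_{i,t}),

with a VAR(p) law of motion for z_t = (Y_t, F_t),

    z_t = C_t + B_{t,1} z_{t-1} + ... + B_{t,p} z_{t-p} + eps_t,
    eps_t ~ N(0, Q_t),

where lambda_t and beta_t = (C_t, B_{t,1..p}) follow Gaussian random walks.
Estimation replaces the random-walk innovation covariances by forgetting
factors k3, k4 (predicted state covariance inflated by 1/k), and V_t, Q_t by
EWMA recursions with decay factors k1, k2; a single forward filtered pass is
followed by a fixed-interval backward smoothing pass.  With k3 = k4 = 1 the
implied state-innovation covariances are exactly zero and the filter reduces
to recursive least squares on a constant-parameter model.

The loading filter runs per observation equation with a scalar observation;
the coefficient filter runs on the stacked state vec(B_t) with observation
matrix I_{l+1} (kron) w_t', w_t = (1, z_{t-1}, ..., z_{t-p}).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .factors import FactorExtractor, FactorSet, build_regressors
from .panel import StandardizedPanel

__all__ = [
    "FilterConfig",
    "FilterState",
    "initialize",
    "predict",
    "ewma_update",
    "kalman_update",
    "smooth_gaussian_paths",
    "smooth_ewma_paths",
    "TVPFAVAR",
    "fit_tvp_favar",
]

_PSD_TOL = 1e-10


@dataclass
class FilterConfig:
    """Filter hyperparameters.

    ``k1, k2`` are EWMA decay factors for the observation and VAR innovation
    covariances; ``k3, k4`` are forgetting factors for the loading and
    coefficient states — all in (0, 1], with 1 meaning no discounting.
    ``init_state_variance`` scales the diffuse diagonal prior on the states;
    ``init_V_scale`` and ``init_Q_scale`` set V_0 and Q_0 (identity scale 1
    by convention).
    """

    lags: int = 2
    k1: float = 0.96
    k2: float = 0.96
    k3: float = 0.99
    k4: float = 0.99
    init_state_variance: float = 10.0
    init_V_scale: float = 1.0
    init_Q_scale: float = 1.0

    def validate(self) -> None:
        if self.lags < 1:
            raise ValueError("lags must be >= 1")
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("init_state_variance", "init_V_scale", "init_Q_scale"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        data = yaml.safe_load(open(path)) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class FilterState:
    """Filter state at one time point.

    ``lam`` (n, k) loading means with per-equation covariances ``Sig_lam``
    (n, k, k); ``beta`` (d,) = vec of the (m, k) coefficient matrix stacked
    column-per-equation, with covariance ``Sig_beta`` (d, d); ``V`` (n,)
    diagonal observation variances; ``Q`` (k, k) VAR innovation covariance.
    """

    lam: np.ndarray
    Sig_lam: np.ndarray
    beta: np.ndarray
    Sig_beta: np.ndarray
    V: np.ndarray
    Q: np.ndarray


def _check_psd(mat: np.ndarray, what: str) -> None:
    sym_err = np.max(np.abs(mat - np.swapaxes(mat, -1, -2)))
    if sym_err > 1e-8:
        raise ValueError(f"{what}: covariance not symmetric (max asymmetry {sym_err:.2e})")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -_PSD_TOL * max(1.0, float(eig.max())):
        raise ValueError(f"{what}: covariance not PSD (min eigenvalue {eig.min():.2e})")


def initialize(config: FilterConfig, n: int, l: int) -> FilterState:
    """Diffuse zero-mean prior with diagonal covariances; V_0 and Q_0 at
    their identity scales."""
    config.validate()
    if n < 1 or l < 1:
        raise ValueError("n and l must be >= 1")
    k = l + 1
    m = 1 + k * config.lags
    d = m * k
    s0 = config.init_state_variance
    return FilterState(
        lam=np.zeros((n, k)),
        Sig_lam=np.broadcast_to(s0 * np.eye(k), (n, k, k)).copy(),
        beta=np.zeros(d),
        Sig_beta=s0 * np.eye(d),
        V=np.full(n, float(config.init_V_scale)),
        Q=config.init_Q_scale * np.eye(k),
    )


def predict(state: FilterState, config: FilterConfig) -> tuple[FilterState, float, float]:
    """One-step state prediction under the forgetting-factor dynamics.

    Means carry over (random-walk prediction); covariances inflate by 1/k3
    (loadings) and 1/k4 (coefficients), equivalent to adding the implied
    innovation covariances W_hat = (1/k3 - 1) Sig_lam and
    R_hat = (1/k4 - 1) Sig_beta.  Returns the predicted state and the
    largest absolute entries of W_hat and R_hat.
    """
    _check_psd(state.Sig_lam, "Sig_lam prior")
    _check_psd(state.Sig_beta, "Sig_beta prior")
    w_gain = 1.0 / config.k3 - 1.0
    r_gain = 1.0 / config.k4 - 1.0
    w_max = float(np.max(np.abs(w_gain * state.Sig_lam)))
    r_max = float(np.max(np.abs(r_gain * state.Sig_beta)))
    return (
        replace(
            state,
            Sig_lam=state.Sig_lam / config.k3,
            Sig_beta=state.Sig_beta / config.k4,
        ),
        w_max,
        r_max,
    )


def ewma_update(
    pred: FilterState,
    x_t: np.ndarray,
    z_t: np.ndarray,
    w_t: np.ndarray | None,
    config: FilterConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EWMA covariance updates from the one-step prediction residuals.

    mu_t = x_t - z_t'lambda_{t|t-1} (per equation) drives V_hat; the VAR
    innovation eps_t = z_t - w_t'B_{t|t-1} drives Q_hat.  ``w_t=None`` (the
    initial-conditions quarters) leaves Q at its prediction and eps at zero.
    Returns (V_hat, Q_hat, mu_t, eps_t).
    """
    mu = x_t - pred.lam @ z_t
    V_hat = config.k1 * pred.V + (1.0 - config.k1) * mu**2
    if w_t is None:
        return V_hat, pred.Q.copy(), mu, np.zeros_like(z_t)
    k = z_t.shape[0]
    B = pred.beta.reshape(len(w_t), k, order="F")
    eps = z_t - B.T @ w_t
    Q_hat = config.k2 * pred.Q + (1.0 - config.k2) * np.outer(eps, eps)
    Q_hat = 0.5 * (Q_hat + Q_hat.T)
    return V_hat, Q_hat, mu, eps


def kalman_update(
    pred: FilterState,
    x_t: np.ndarray,
    z_t: np.ndarray,
    w_t: np.ndarray | None,
    V_hat: np.ndarray,
    Q_hat: np.ndarray,
) -> FilterState:
    """Measurement update of loadings and coefficients at time t."""
    # --- loadings: scalar observation per equation, vectorized over i ----
    mu = x_t - pred.lam @ z_t
    s = pred.Sig_lam @ z_t  # (n, k)
    f = V_hat + s @ z_t  # innovation variances (n,)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        bad = int(np.argmin(f))
        raise np.linalg.LinAlgError(
            f"singular innovation variance in loading update (equation {bad}, f={f[bad]:.3e})"
        )
    K = s / f[:, None]
    lam = pred.lam + K * mu[:, None]
    Sig_lam = pred.Sig_lam - K[:, :, None] * s[:, None, :]
    Sig_lam = 0.5 * (Sig_lam + np.swapaxes(Sig_lam, 1, 2))

    if w_t is None:
        return FilterState(lam, Sig_lam, pred.beta.copy(), pred.Sig_beta.copy(), V_hat, Q_hat)

    # --- coefficients: stacked vec(B) state, observation I_k kron w' -----
    k = z_t.shape[0]
    H = np.kron(np.eye(k), w_t)  # (k, d)
    B = pred.beta.reshape(len(w_t), k, order="F")
    eps = z_t - B.T @ w_t
    SHt = pred.Sig_beta @ H.T  # (d, k)
    F = Q_hat + H @ SHt
    F = 0.5 * (F + F.T)
    try:
        Kb = np.linalg.solve(F, SHt.T).T  # (d, k)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance in coefficient update: {exc}"
        ) from exc
    beta = pred.beta + Kb @ eps
    Sig_beta = pred.Sig_beta - Kb @ SHt.T
    Sig_beta = 0.5 * (Sig_beta + Sig_beta.T)
    return FilterState(lam, Sig_lam, beta, Sig_beta, V_hat, Q_hat)


def _smoother_gain(Sig_filt: np.ndarray, Sig_pred_next: np.ndarray) -> np.ndarray:
    """C_t = Sig_{t|t} (Sig_{t+1|t})^{-1}, pseudo-inverse fallback if singular."""
    try:
        return np.linalg.solve(Sig_pred_next.T, Sig_filt.T).T
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular predicted covariance in smoother; using pseudo-inverse")
        return Sig_filt @ np.linalg.pinv(Sig_pred_next)


def smooth_gaussian_paths(
    means: np.ndarray, covs: np.ndarray, kappa: float, t0: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-interval (RTS) smoother for a random-walk state filtered with
    forgetting factor ``kappa``.

    ``means`` is (T, ...) filtered means, ``covs`` the matching filtered
    covariances with matrix dimensions last.  Under the forgetting dynamics
    the prediction is mean_{t+1|t} = mean_{t|t}, Sig_{t+1|t} = Sig_{t|t}/kappa,
    so the smoother gain is C_t = Sig_{t|t} Sig_{t+1|t}^{-1}.  Entries before
    ``t0`` (initial conditions never updated) are backfilled with the value
    at ``t0``.
    """
    T = means.shape[0]
    sm_means = means.copy()
    sm_covs = covs.copy()
    for t in range(T - 2, t0 - 1, -1):
        Sig_pred_next = covs[t] / kappa
        if covs.ndim == 4:  # per-equation batch (n, k, k)
            for i in range(covs.shape[1]):
                C = _smoother_gain(covs[t, i], Sig_pred_next[i])
                sm_means[t, i] = means[t, i] + C @ (sm_means[t + 1, i] - means[t, i])
                sm_covs[t, i] = covs[t, i] + C @ (sm_covs[t + 1, i] - Sig_pred_next[i]) @ C.T
                sm_covs[t, i] = 0.5 * (sm_covs[t, i] + sm_covs[t, i].T)
        else:
            C = _smoother_gain(covs[t], Sig_pred_next)
            sm_means[t] = means[t] + C @ (sm_means[t + 1] - means[t])
            sm_covs[t] = covs[t] + C @ (sm_covs[t + 1] - Sig_pred_next) @ C.T
            sm_covs[t] = 0.5 * (sm_covs[t] + sm_covs[t].T)
    sm_means[:t0] = sm_means[t0]
    sm_covs[:t0] = sm_covs[t0]
    return sm_means, sm_covs


def smooth_ewma_paths(path: np.ndarray, decay: float, t0: int = 0) -> np.ndarray:
    """Backward harmonic smoothing of an EWMA covariance path.

    Inverse-weighted recursion  M_{t|T}^{-1} = decay * M_{t|t}^{-1}
    + (1-decay) * M_{t+1|T}^{-1},  applied elementwise for diagonal paths
    (T, n) and matrix-wise for (T, k, k) paths.
    """
    sm = path.copy()
    T = path.shape[0]
    if path.ndim == 2:
        for t in range(T - 2, t0 - 1, -1):
            sm[t] = 1.0 / (decay / path[t] + (1.0 - decay) / sm[t + 1])
    else:
        for t in range(T - 2, t0 - 1, -1):
            inv = decay * np.linalg.inv(path[t]) + (1.0 - decay) * np.linalg.inv(sm[t + 1])
            sm[t] = np.linalg.inv(inv)
            sm[t] = 0.5 * (sm[t] + sm[t].T)
    sm[:t0] = sm[t0]
    return sm


class TVPFAVAR(BaseEstimator):
    """Time-varying-parameter FAVAR estimated by forgetting-factor filtering.

    Parameters
    ----------
    n_factors : int
        Number of principal-component factors extracted from the observation
        block (full-sample, two-step).
    lags : int
        VAR lag order p.
    k1, k2 : float in (0, 1]
        EWMA decay factors for the observation variances V_t and the VAR
        innovation covariance Q_t.
    k3, k4 : float in (0, 1]
        Forgetting factors for the loading and coefficient states; 1 gives
        constant-parameter recursive least squares.
    init_state_variance, init_V_scale, init_Q_scale : float
        Prior scales (diagonal priors; V_0 and Q_0 default to identity).

    Attributes (after ``fit``)
    --------------------------
    ``lambda_filtered_``/``lambda_smoothed_`` (T, n, l+1);
    ``Sigma_lambda_*_`` (T, n, l+1, l+1); ``beta_filtered_``/
    ``beta_smoothed_`` (T, d); ``Sigma_beta_*_`` (T, d, d);
    ``V_*_`` (T, n); ``Q_*_`` (T, l+1, l+1); residuals ``mu_`` (T, n) and
    ``eps_`` (T, l+1); ``Z_`` (T, l+1) regressors with growth first;
    ``max_abs_W_hat_``/``max_abs_R_hat_`` — largest absolute entry of the
    implied state-innovation covariances over the whole pass.
    """

    def __init__(
        self,
        n_factors: int = 3,
        lags: int = 2,
        k1: float = 0.96,
        k2: float = 0.96,
        k3: float = 0.99,
        k4: float = 0.99,
        init_state_variance: float = 10.0,
        init_V_scale: float = 1.0,
        init_Q_scale: float = 1.0,
    ):
        self.n_factors = n_factors
        self.lags = lags
        self.k1 = k1
        self.k2 = k2
        self.k3 = k3
        self.k4 = k4
        self.init_state_variance = init_state_variance
        self.init_V_scale = init_V_scale
        self.init_Q_scale = init_Q_scale

    # ------------------------------------------------------------------
    def _config(self) -> FilterConfig:
        cfg = FilterConfig(
            lags=self.lags,
            k1=self.k1,
            k2=self.k2,
            k3=self.k3,
            k4=self.k4,
            init_state_variance=self.init_state_variance,
            init_V_scale=self.init_V_scale,
            init_Q_scale=self.init_Q_scale,
        )
        cfg.validate()
        return cfg

    def fit(self, X, y, Z=None) -> "TVPFAVAR":
        """Estimate the time-varying parameter paths.

        ``X`` is the T x n standardized indicator panel, ``y`` the length-T
        growth series.  ``Z`` optionally supplies a precomputed regressor
        path (growth first) and bypasses factor extraction.
        """
        config = self._config()
        if hasattr(X, "columns"):
            self.target_names_ = list(X.columns)
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        T, n = X.shape
        if len(y) != T:
            raise ValueError("X and y must have the same number of time points")
        p = config.lags
        if T <= p + 2:
            raise ValueError(f"need T > lags + 2 = {p + 2}, got T = {T}")
        if not hasattr(self, "target_names_") or len(self.target_names_) != n:
            self.target_names_ = [f"x{i:02d}" for i in range(n)]

        if Z is not None:
            Z = check_array(Z, dtype=float)
            if Z.shape[0] != T:
                raise ValueError("Z length mismatch")
            self.factor_extractor_ = None
        else:
            fe = FactorExtractor(n_factors=self.n_factors)
            F = fe.fit_transform(X)
            self.factor_extractor_ = fe
            Z = np.hstack([y[:, None], F])
        k = Z.shape[1]
        l = k - 1
        m = 1 + k * p
        d = m * k

        state = initialize(config, n, l)
        lam_f = np.empty((T, n, k))
        Sig_lam_f = np.empty((T, n, k, k))
        beta_f = np.empty((T, d))
        Sig_beta_f = np.empty((T, d, d))
        V_f = np.empty((T, n))
        Q_f = np.empty((T, k, k))
        mu = np.zeros((T, n))
        eps = np.zeros((T, k))
        w_max = r_max = 0.0

        for t in range(T):
            pred, wm, rm = predict(state, config)
            w_max, r_max = max(w_max, wm), max(r_max, rm)
            if t < p:
                # initial-conditions quarters: lambda filter only
                pred = replace(pred, Sig_beta=state.Sig_beta)
                w_t = None
            else:
                w_t = np.concatenate([[1.0]] + [Z[t - j] for j in range(1, p + 1)])
            V_hat, Q_hat, mu[t], eps[t] = ewma_update(pred, X[t], Z[t], w_t, config)
            state = kalman_update(pred, X[t], Z[t], w_t, V_hat, Q_hat)
            lam_f[t], Sig_lam_f[t] = state.lam, state.Sig_lam
            beta_f[t], Sig_beta_f[t] = state.beta, state.Sig_beta
            V_f[t], Q_f[t] = state.V, state.Q

        lam_s, Sig_lam_s = smooth_gaussian_paths(lam_f, Sig_lam_f, config.k3)
        beta_s, Sig_beta_s = smooth_gaussian_paths(beta_f, Sig_beta_f, config.k4, t0=p)
        V_s = smooth_ewma_paths(V_f, config.k1)
        Q_s = smooth_ewma_paths(Q_f, config.k2, t0=p)

        self.n_features_in_ = n
        self.T_, self.k_, self.l_, self.m_, self.d_ = T, k, l, m, d
        self.Z_ = Z
        self.lambda_filtered_, self.lambda_smoothed_ = lam_f, lam_s
        self.Sigma_lambda_filtered_, self.Sigma_lambda_smoothed_ = Sig_lam_f, Sig_lam_s
        self.beta_filtered_, self.beta_smoothed_ = beta_f, beta_s
        self.Sigma_beta_filtered_, self.Sigma_beta_smoothed_ = Sig_beta_f, Sig_beta_s
        self.V_filtered_, self.V_smoothed_ = V_f, V_s
        self.Q_filtered_, self.Q_smoothed_ = Q_f, Q_s
        self.mu_, self.eps_ = mu, eps
        self.max_abs_W_hat_, self.max_abs_R_hat_ = w_max, r_max
        return self

    # ------------------------------------------------------------------
    def beta_matrix(self, t: int, smoothed: bool = True) -> np.ndarray:
        """Coefficient matrix B_t of shape (m, l+1): intercept row first,
        then the p lag blocks (transposed), one column per equation."""
        check_is_fitted(self, "beta_smoothed_")
        beta = self.beta_smoothed_ if smoothed else self.beta_filtered_
        return beta[t].reshape(self.m_, self.k_, order="F")

    def validate_psd(self, tol: float = _PSD_TOL) -> None:
        """Check every stored covariance is symmetric PSD (test support)."""
        check_is_fitted(self, "beta_smoothed_")
        for name in (
            "Sigma_lambda_filtered_",
            "Sigma_lambda_smoothed_",
            "Sigma_beta_filtered_",
            "Sigma_beta_smoothed_",
            "Q_filtered_",
            "Q_smoothed_",
        ):
            arr = getattr(self, name)
            eig = np.linalg.eigvalsh(arr)
            if eig.min() < -tol * max(1.0, float(eig.max())):
                raise AssertionError(f"{name}: min eigenvalue {eig.min():.2e}")
        if self.V_filtered_.min() <= 0 or self.V_smoothed_.min() <= 0:
            raise AssertionError("V path not positive")

    def irf(self, t: int, horizon: int = 12, shock: str = "growth",
            targets: list[str] | None = None, smoothed: bool = True) -> np.ndarray:
        """Impulse responses of observed indicators at origin ``t``; see
        :mod:`tvpfavar.irf`."""
        from . import irf as _irf

        return _irf.irf_observables(self, t, horizon, targets, smoothed=smoothed)

    def irf_surface(self, horizon: int = 12, targets: list[str] | None = None):
        from . import irf as _irf

        return _irf.irf_surface(self, horizon, targets)

    def save(self, path) -> None:
        """Serialize the state paths as a compressed archive + JSON index."""
        import json
        from pathlib import Path

        check_is_fitted(self, "beta_smoothed_")
        arrays = {
            name: getattr(self, name)
            for name in (
                "Z_",
                "lambda_filtered_",
                "lambda_smoothed_",
                "beta_filtered_",
                "beta_smoothed_",
                "Sigma_lambda_filtered_",
                "Sigma_lambda_smoothed_",
                "Sigma_beta_filtered_",
                "Sigma_beta_smoothed_",
                "V_filtered_",
                "V_smoothed_",
                "Q_filtered_",
                "Q_smoothed_",
                "mu_",
                "eps_",
            )
        }
        path = Path(path)
        np.savez_compressed(path, **arrays)
        index = {k: list(v.shape) for k, v in arrays.items()}
        index["params"] = self.get_params()
        index["targets"] = self.target_names_
        path.with_suffix(".json").write_text(json.dumps(index, indent=1))


def fit_tvp_favar(
    panel: StandardizedPanel, factors: FactorSet | None, config: FilterConfig
) -> TVPFAVAR:
    """Functional entry point: fit on a panel with precomputed factors."""
    Z = build_regressors(panel, factors)
    model = TVPFAVAR(
        n_factors=0 if factors is None else factors.n_factors,
        lags=config.lags,
        k1=config.k1,
        k2=config.k2,
        k3=config.k3,
        k4=config.k4,
        init_state_variance=config.init_state_variance,
        init_V_scale=config.init_V_scale,
        init_Q_scale=config.init_Q_scale,
    )
    model.target_names_ = list(panel.X.columns)
    return model.fit(panel.X.to_numpy(), panel.Y.to_numpy(), Z=Z)
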