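"""Synthetic data generation.

Three generators:

* :func:`simulate_tvp_favar` — exact draws from the TVP-FAVAR data-generating
  process (observation equation with time-varying loadings; VAR law of motion
  for the latent factors and growth; random-walk loadings and coefficients),
  with the full parameter paths recorded as ground truth.
* :func:`simulate_raw_panel` — a mixed-frequency raw panel emulating a
  74-dimensional quarterly macro dataset with nine annual health indicators
  calibrated to published descriptive statistics of the Chinese 2005–2017
  sample, for exercising the preprocessing pipeline.
* :func:`simulate_regime_correlation` — a bivariate series with GARCH(1,1)
  margins and piecewise-constant conditional correlation, the test fixture
  for the DCC estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import RawPanel, RawSeries, StandardizedPanel

__all__ = [
    "DgpConfig",
    "SyntheticTruth",
    "RegimeCorrConfig",
    "simulate_tvp_favar",
    "simulate_raw_panel",
    "simulate_regime_correlation",
    "HEALTH_CALIBRATION",
    "GROWTH_CALIBRATION",
]

# (mean, sd) targets per health indicator, matching the descriptive
# statistics of the empirical sample the generator emulates.
HEALTH_CALIBRATION: dict[str, tuple[float, float]] = {
    "mortality": (7.032308, 0.184227),
    "infectious_mortality": (1.108354, 0.186766),
    "medical_expenditure": (6.409124, 0.343598),
    "infant_mortality": (12.03615, 3.784469),
    "traffic_accident": (2.517749, 0.021671),
    "mental_illness": (14.42963, 0.690913),
    "tumor_mortality": (14.77865, 0.693899),
    "occupational_disease": (10.95118, 0.578461),
    "cardiovascular": (10.16806, 0.116526),
}

GROWTH_CALIBRATION: tuple[float, float] = (9.309091, 2.482420)

_MAX_STABILITY_RETRIES = 5
_TARGET_SPECTRAL_RADIUS = 0.95


@dataclass
class DgpConfig:
    """Configuration of the TVP-FAVAR data-generating process.

    ``n_obs_series`` observed indicators load on ``z_t = (Y_t, F_t)`` where
    ``F_t`` holds ``n_factors`` latent factors and ``Y_t`` is the single
    growth variable; ``(F_t, Y_t)`` jointly follow a VAR(``lags``) whose
    coefficients and the loadings evolve as Gaussian random walks.
    """

    n_obs_series: int = 20
    n_factors: int = 3
    lags: int = 2
    T: int = 200
    loading_innovation_sd: float = 0.01
    coef_innovation_sd: float = 0.01
    obs_noise_sd: float = 0.5
    var_noise_scale: float = 1.0
    seed: int = 0
    n_growth: int = field(default=1, init=False)  # fixed by the model

    def validate(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.lags < 1:
            raise ValueError("lags must be >= 1")
        if self.T <= self.lags:
            raise ValueError("T must exceed the lag order")
        if self.n_obs_series < 1:
            raise ValueError("n_obs_series must be >= 1")
        for name in ("loading_innovation_sd", "coef_innovation_sd", "obs_noise_sd", "var_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def state_dim(self) -> int:
        """Dimension of z_t = (Y_t, F_t)."""
        return self.n_factors + 1


@dataclass
class SyntheticTruth:
    """Recorded ground-truth parameter paths of a simulated TVP-FAVAR draw.

    Shapes: ``lambda_path`` (T, n, l+1); ``beta_path`` (T, m, l+1) with
    m = 1 + (l+1)p, rows ordered (intercept, lag-1 block, ..., lag-p block);
    ``factor_path`` (T, l); ``obs_cov_path`` (T, n) diagonal of V_t;
    ``var_cov_path`` (T, l+1, l+1) = Q_t.
    """

    lambda_path: np.ndarray
    beta_path: np.ndarray
    factor_path: np.ndarray
    obs_cov_path: np.ndarray
    var_cov_path: np.ndarray

    def save(self, path: str | Path) -> None:
        """Serialize as a compressed flat-array archive plus a JSON index."""
        path = Path(path)
        arrays = {
            "lambda_path": self.lambda_path,
            "beta_path": self.beta_path,
            "factor_path": self.factor_path,
            "obs_cov_path": self.obs_cov_path,
            "var_cov_path": self.var_cov_path,
        }
        np.savez_compressed(path, **arrays)
        index = {k: list(v.shape) for k, v in arrays.items()}
        path.with_suffix(".json").write_text(json.dumps(index, indent=1))


def _companion(blocks: list[np.ndarray]) -> np.ndarray:
    """Companion matrix of a VAR(p) given its p coefficient blocks (k x k)."""
    k = blocks[0].shape[0]
    p = len(blocks)
    A = np.zeros((k * p, k * p))
    A[:k, :] = np.hstack(blocks)
    if p > 1:
        A[k:, :-k] = np.eye(k * (p - 1))
    return A


def _spectral_radius(mat: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(mat))))


def _draw_stable_var(rng: np.random.Generator, k: int, p: int) -> list[np.ndarray]:
    """Draw VAR blocks and rescale so the companion spectral radius is <= 0.95.

    Scaling lag-j blocks by c**j maps every companion eigenvalue mu to c*mu,
    so one rescale guarantees stability.
    """
    for _ in range(_MAX_STABILITY_RETRIES):
        blocks = [0.5 * np.eye(k) + rng.normal(0.0, 0.1, (k, k))]
        blocks += [rng.normal(0.0, 0.1 / j, (k, k)) for j in range(2, p + 1)]
        rho = _spectral_radius(_companion(blocks))
        if rho > _TARGET_SPECTRAL_RADIUS:
            c = _TARGET_SPECTRAL_RADIUS / rho
            blocks = [b * c ** (j + 1) for j, b in enumerate(blocks)]
        if _spectral_radius(_companion(blocks)) < 1.0:
            return blocks
    raise RuntimeError("failed to draw a stable VAR after retries")  # pragma: no cover


def _step_beta(
    rng: np.random.Generator, prev: np.ndarray, sd: float, p: int, k: int
) -> np.ndarray:
    """One random-walk step of the coefficient path, rejecting explosive draws.

    An unconstrained random walk leaves the stationarity region almost
    surely at these innovation scales, making the simulated panel explode;
    the conventional fix is to resample the innovation until the companion
    spectral radius stays below 1 (here 0.97, matching the draw-time
    ceiling).  After ``_MAX_STABILITY_RETRIES * 20`` rejected draws the step
    is skipped (zero innovation), keeping the path inside the region.
    """
    if sd == 0.0:
        return prev.copy()
    m = prev.shape[0]
    for _ in range(_MAX_STABILITY_RETRIES * 20):
        cand = prev + rng.normal(0.0, sd, (m, k))
        blocks = [cand[1 + j * k : 1 + (j + 1) * k, :].T for j in range(p)]
        if _spectral_radius(_companion(blocks)) < 0.97:
            return cand
    return prev.copy()


def simulate_tvp_favar(config: DgpConfig) -> tuple[StandardizedPanel, SyntheticTruth]:
    """Draw one panel from the TVP-FAVAR DGP, recording the parameter paths.

    Returns the observation panel (X with columns ``x00..``, Y = the growth
    coordinate of the simulated state) and a :class:`SyntheticTruth` holding
    lambda_t, beta_t, F_t, V_t and Q_t for every t.  Identical configs
    (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, l, p, T = config.n_obs_series, config.n_factors, config.lags, config.T
    k = l + 1  # z_t = (Y_t, F_1..F_l)
    m = 1 + k * p

    # -- parameter paths -------------------------------------------------
    blocks0 = _draw_stable_var(rng, k, p)
    beta0 = np.zeros((m, k))  # columns = equations; row 0 = intercept
    for j, B in enumerate(blocks0):
        beta0[1 + j * k : 1 + (j + 1) * k, :] = B.T
    lam0 = rng.normal(0.0, 1.0, (n, k))

    beta_path = np.empty((T, m, k))
    lam_path = np.empty((T, n, k))
    beta_path[0], lam_path[0] = beta0, lam0
    for t in range(1, T):
        beta_path[t] = _step_beta(rng, beta_path[t - 1], config.coef_innovation_sd, p, k)
        lam_path[t] = lam_path[t - 1] + rng.normal(0.0, config.loading_innovation_sd, (n, k))

    # -- state recursion -------------------------------------------------
    burn = 4 * p + 24
    z_hist = np.zeros((burn + T, k))
    for t in range(p, burn + T):
        idx = min(max(t - burn, 0), T - 1)
        B = beta_path[idx]
        w = np.concatenate([[1.0]] + [z_hist[t - j] for j in range(1, p + 1)])
        eps = rng.normal(0.0, config.var_noise_scale, k)
        z_hist[t] = w @ B + eps
    z = z_hist[burn:]

    # -- observation equation -------------------------------------------
    noise = rng.normal(0.0, config.obs_noise_sd, (T, n))
    X = np.einsum("tnk,tk->tn", lam_path, z) + noise

    quarters = pd.period_range("2005Q1", periods=T, freq="Q")
    cols = [f"x{i:02d}" for i in range(n)]
    panel = StandardizedPanel(
        quarters=quarters,
        X=pd.DataFrame(X, index=quarters, columns=cols),
        Y=pd.Series(z[:, 0], index=quarters, name="growth"),
        transform_log={c: ["simulated"] for c in cols},
    )
    truth = SyntheticTruth(
        lambda_path=lam_path,
        beta_path=beta_path,
        factor_path=z[:, 1:].copy(),
        obs_cov_path=np.full((T, n), config.obs_noise_sd**2),
        var_cov_path=np.broadcast_to(
            config.var_noise_scale**2 * np.eye(k), (T, k, k)
        ).copy(),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Raw mixed-frequency panel
# ---------------------------------------------------------------------------


def _ar1(rng: np.random.Generator, T: int, phi: float) -> np.ndarray:
    """Zero-mean unit-variance stationary AR(1) path."""
    e = rng.normal(0.0, np.sqrt(1.0 - phi**2), T)
    x = np.empty(T)
    x[0] = rng.normal(0.0, 1.0)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + e[t]
    return x


def simulate_raw_panel(
    seed: int,
    n_macro: int = 64,
    start: str = "2005Q1",
    end: str = "2017Q4",
    health_growth_coupling: float = 0.4,
) -> RawPanel:
    """Generate a mixed-frequency raw panel emulating the empirical dataset.

    One quarterly growth series (GDP growth, unconditional mean 9.31, sd
    2.48), nine annual health indicators whose latent quarterly processes are
    calibrated to the published per-series means and standard deviations
    (annual value = mean of the year's four quarters, so interpolation has a
    recoverable truth), and ``n_macro`` >= 60 quarterly macro series driven
    by three common AR(1) factors — a subset with unit roots, a subset with
    deterministic quarterly seasonality, and a subset of positive level
    series flagged for log transformation.
    """
    if n_macro < 60:
        raise ValueError("n_macro must be >= 60 to emulate the 74-dimensional panel")
    rng = np.random.default_rng(seed)
    quarters = pd.period_range(start, end, freq="Q")
    T = len(quarters)
    years = pd.period_range(quarters[0].asfreq("Y"), quarters[-1].asfreq("Y"), freq="Y")
    if T % 4 != 0:
        raise ValueError("sample must cover whole years")

    series: list[RawSeries] = []

    # growth: stationary AR(1) around the calibrated mean
    g_mean, g_sd = GROWTH_CALIBRATION
    g_std = _ar1(rng, T, phi=0.8)
    growth = g_mean + g_sd * g_std
    series.append(
        RawSeries("growth", "growth", "quarterly", pd.Series(growth, index=quarters, name="growth"))
    )

    # health indicators: latent quarterly process partly driven by growth,
    # observed annually as the mean of each year's quarters
    w = health_growth_coupling
    for name, (mu, sd) in HEALTH_CALIBRATION.items():
        latent = mu + sd * (w * g_std + np.sqrt(1.0 - w**2) * _ar1(rng, T, phi=0.9))
        annual = latent.reshape(-1, 4).mean(axis=1)
        series.append(
            RawSeries(name, "health", "annual", pd.Series(annual, index=years, name=name))
        )

    # macro block: common factor structure + idiosyncratic features
    n_factors = 3
    F = np.column_stack([_ar1(rng, T, phi=0.7) for _ in range(n_factors)])
    loadings = rng.normal(0.0, 1.0, (n_macro, n_factors))
    season_pattern = np.array([1.0, 0.0, -1.0, 0.0])
    for j in range(n_macro):
        x = F @ loadings[j] + 0.5 * rng.normal(0.0, 1.0, T)
        log_flag = False
        if j % 5 == 4:  # nonstationary level series
            x = np.cumsum(0.3 * x) + rng.normal(0.0, 0.1, T)
        if j % 4 == 3:  # deterministic quarterly seasonality
            amp = rng.uniform(0.5, 1.5)
            x = x + amp * np.tile(season_pattern, T // 4)
        if j % 6 == 5:  # positive level series, flagged for logs
            x = np.exp(0.2 * x + 3.0)
            log_flag = True
        series.append(
            RawSeries(
                f"macro{j:02d}",
                "macro",
                "quarterly",
                pd.Series(x, index=quarters, name=f"macro{j:02d}"),
                log_flag=log_flag,
            )
        )
    return RawPanel(series=series)


# ---------------------------------------------------------------------------
# Regime-correlation fixture for the DCC estimator
# ---------------------------------------------------------------------------


@dataclass
class RegimeCorrConfig:
    """Bivariate GARCH(1,1) margins with piecewise-constant true correlation.

    ``rho_segments`` is a list of (start, end, rho) with 1-based inclusive
    bounds that must partition 1..T; each |rho| < 1.
    """

    T: int = 400
    rho_segments: tuple[tuple[int, int, float], ...] = ((1, 200, -0.8), (201, 400, 0.8))
    garch_omega: float = 0.05
    garch_alpha: float = 0.1
    garch_beta: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.garch_omega < 0 or self.garch_alpha < 0 or self.garch_beta < 0:
            raise ValueError("GARCH parameters must be nonnegative")
        if self.garch_alpha + self.garch_beta >= 1.0:
            raise ValueError("alpha + beta must be < 1 for covariance stationarity")
        pos = 1
        for start, end, rho in self.rho_segments:
            if start != pos or end < start:
                raise ValueError("rho_segments must partition 1..T in order")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"target correlation {rho} must lie strictly in (-1, 1)")
            pos = end + 1
        if pos != self.T + 1:
            raise ValueError("rho_segments must partition 1..T")


def simulate_regime_correlation(
    config: RegimeCorrConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the bivariate regime-correlation fixture.

    Returns ``(pair, true_rho_path)`` where ``pair`` is (T, 2) returns with
    GARCH(1,1) conditional variances and ``true_rho_path`` the length-T
    piecewise-constant conditional correlation of the innovations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = config.T
    rho_path = np.empty(T)
    for start, end, rho in config.rho_segments:
        rho_path[start - 1 : end] = rho

    omega, alpha, beta = config.garch_omega, config.garch_alpha, config.garch_beta
    h = np.full(2, omega / (1.0 - alpha - beta))
    pair = np.empty((T, 2))
    for t in range(T):
        z1 = rng.normal()
        z2 = rho_path[t] * z1 + np.sqrt(1.0 - rho_path[t] ** 2) * rng.normal()
        pair[t] = np.sqrt(h) * np.array([z1, z2])
        h = omega + alpha * pair[t] ** 2 + beta * h
    return pair, rho_path
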