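"""Five-step data-preparation protocol for the mixed-frequency panel.

Per series, in order: (1) annual-to-quarterly quadratic-spline interpolation,
(2) log transform of flagged level series, (3) additive seasonal adjustment
by quarterly-dummy centering, (4) unit-root screening with the no-constant /
no-trend augmented Dickey-Fuller rule and first differencing of nonstationary
series, (5) standardization to mean 0 / sd 1.  :func:`build_panel` applies
the full protocol and trims everything to the common quarterly window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .panel import RawPanel, RawSeries, StandardizedPanel

__all__ = [
    "PreprocessConfig",
    "annual_to_quarterly",
    "seasonal_adjust",
    "adf_is_stationary",
    "standardize",
    "build_panel",
    "PanelPreprocessor",
]


@dataclass
class PreprocessConfig:
    """Knobs of the preparation protocol.

    ``adf_max_lag`` is the fixed augmentation order of the Dickey-Fuller
    regression (4 = one year of quarterly lags).  ``adf_variant`` selects
    the panel screen: ``"raw"`` applies the no-constant rule to the series
    as is (nonzero-mean levels are then differenced — growth-rate semantics
    for logged levels); ``"centered"`` demeans first (note the no-constant
    critical values over-reject the unit root on demeaned data); ``"both"``
    (default) requires passing on both scales, so a series is differenced
    unless its stationarity is unambiguous with and without the level
    removed — and the standardized output panel is guaranteed to pass the
    screen on its own (centered) scale.  ``on_still_nonstationary`` decides
    what happens to a series that fails again after one difference.
    """

    adf_max_lag: int = 4
    adf_variant: Literal["both", "raw", "centered"] = "both"
    on_still_nonstationary: Literal["drop", "second_difference", "keep"] = "drop"


def annual_to_quarterly(series: RawSeries) -> RawSeries:
    """Disaggregate an annual series to quarterly by mean-matching quadratics.

    One quadratic per year on local time tau in [0, 1]; quarterly values are
    point evaluations at tau = 1/8, 3/8, 5/8, 7/8.  Constraints: each year's
    four quarters average exactly to the annual value; value and slope are
    continuous across year boundaries; natural (zero-curvature) conditions at
    both ends close the system.  Preserving each year's mean keeps annual
    totals of rate/level indicators intact, the standard requirement in
    temporal disaggregation.
    """
    if series.frequency != "annual":
        raise ValueError(f"{series.series_id}: annual_to_quarterly requires an annual series")
    v = series.values.to_numpy(dtype=float)
    N = len(v)
    if N < 3:
        raise ValueError(f"{series.series_id}: need >= 3 annual observations, got {N}")

    tau = np.array([1, 3, 5, 7]) / 8.0
    mean_tau, mean_tau2 = tau.mean(), (tau**2).mean()

    # unknowns (a_i, b_i, c_i) per year; rows: N mean-match, N-1 continuity,
    # N-1 slope continuity, 2 natural boundary conditions
    A = np.zeros((3 * N, 3 * N))
    rhs = np.zeros(3 * N)
    for i in range(N):
        A[i, 3 * i : 3 * i + 3] = [1.0, mean_tau, mean_tau2]
        rhs[i] = v[i]
    r = N
    for i in range(N - 1):
        A[r, 3 * i : 3 * i + 3] = [1.0, 1.0, 1.0]
        A[r, 3 * (i + 1)] = -1.0
        r += 1
    for i in range(N - 1):
        A[r, 3 * i + 1 : 3 * i + 3] = [1.0, 2.0]
        A[r, 3 * (i + 1) + 1] = -1.0
        r += 1
    A[r, 2] = 1.0
    A[r + 1, 3 * (N - 1) + 2] = 1.0
    coef = np.linalg.solve(A, rhs).reshape(N, 3)

    quarters = coef[:, 0:1] + coef[:, 1:2] * tau + coef[:, 2:3] * tau**2
    start = series.values.index[0].asfreq("Q", how="start")
    qidx = pd.period_range(start, periods=4 * N, freq="Q")
    return RawSeries(
        series_id=series.series_id,
        role=series.role,
        frequency="quarterly",
        values=pd.Series(quarters.ravel(), index=qidx, name=series.series_id),
        log_flag=series.log_flag,
    )


def seasonal_adjust(series: RawSeries) -> RawSeries:
    """Remove additive quarter effects by per-quarter mean centering.

    Equivalent to regressing on four quarterly dummies and subtracting the
    fitted quarter effects expressed as deviations from the overall mean;
    the overall mean is preserved exactly and the operation is idempotent.
    """
    if series.frequency != "quarterly":
        raise ValueError(f"{series.series_id}: seasonal_adjust requires a quarterly series")
    vals = series.values
    if len(vals) < 12:
        raise ValueError(f"{series.series_id}: need at least 3 full years for seasonal adjustment")
    q = vals.index.quarter
    overall = vals.to_numpy().mean()
    adj = vals.to_numpy(dtype=float).copy()
    for quarter in (1, 2, 3, 4):
        mask = q == quarter
        adj[mask] -= adj[mask].mean() - overall
    return RawSeries(
        series_id=series.series_id,
        role=series.role,
        frequency="quarterly",
        values=pd.Series(adj, index=vals.index, name=series.series_id),
        log_flag=series.log_flag,
    )


def adf_is_stationary(values: np.ndarray, max_lag: int = 4) -> tuple[float, bool]:
    """No-constant, no-trend augmented Dickey-Fuller screen.

    Regresses the first difference on the lagged level and ``max_lag`` lagged
    differences with neither intercept nor trend; the series is declared
    stationary when the t-statistic on the lagged level falls below the 5%
    critical value of the no-constant case.
    """
    values = np.asarray(values, dtype=float)
    if len(values) <= max_lag + 2:
        raise ValueError("series too short for the requested ADF lag order")
    if np.std(values) == 0.0:
        raise ValueError("zero-variance series: ADF regression is degenerate")
    out = adfuller(values, maxlag=max_lag, regression="n", autolag=None)
    stat, crit = out[0], out[4]
    return float(stat), bool(stat < crit["5%"])


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale to mean 0, sample sd 1 (T-1 denominator)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant series")
    return (values - values.mean()) / sd


def _prepare_series(s: RawSeries, config: PreprocessConfig) -> tuple[pd.Series, list[str]]:
    """Steps (1)-(3): interpolate, log, seasonally adjust one series."""
    log: list[str] = []
    if s.frequency == "annual":
        s = annual_to_quarterly(s)
        log.append("interpolate:quadratic-spline")
    vals = s.values.astype(float)
    if s.log_flag:
        if (vals <= 0).any():
            raise ValueError(f"{s.series_id}: log transform requires positive values")
        vals = np.log(vals)
        log.append("log")
    s = RawSeries(s.series_id, s.role, "quarterly", vals, log_flag=False)
    s = seasonal_adjust(s)
    log.append("seasonal_adjust:quarterly-dummies")
    return s.values, log


def build_panel(raw: RawPanel, config: PreprocessConfig | None = None) -> StandardizedPanel:
    """Run the full five-step protocol over a raw panel.

    Steps (1)-(3) apply per series; the unit-root screen (4) runs on the
    common quarterly window and is iterated, because each differencing
    shrinks the window by one quarter and the screen must hold on the final
    sample every column ends up with.  Differencing is capped at one by
    default; a series failing again is dropped (or second-differenced /
    kept, per config — the growth series is always kept).  Standardization
    (5) happens last.  Every applied step lands in ``transform_log``.
    """
    config = config or PreprocessConfig()
    prepared: dict[str, pd.Series] = {}
    logs: dict[str, list[str]] = {}
    for s in raw.series:
        vals, log = _prepare_series(s, config)
        logs[s.series_id] = log
        prepared[s.series_id] = vals
    roles = {s.series_id: s.role for s in raw.series}
    growth_id = raw.growth.series_id
    max_diffs = 2 if config.on_still_nonstationary == "second_difference" else 1
    n_diffs = {sid: 0 for sid in prepared}

    def _decision(arr: np.ndarray) -> bool:
        raw_ok = adf_is_stationary(arr, max_lag=config.adf_max_lag)[1]
        if config.adf_variant == "raw":
            return raw_ok
        centered_ok = adf_is_stationary(arr - arr.mean(), max_lag=config.adf_max_lag)[1]
        if config.adf_variant == "centered":
            return centered_ok
        return raw_ok and centered_ok

    # iterate the stationarity screen on the shrinking common window
    settled: set[str] = set()
    while True:
        start = max(v.index[0] for v in prepared.values())
        end = min(v.index[-1] for v in prepared.values())
        if start > end:
            raise ValueError("series do not overlap on a common quarterly window")
        changed = False
        for sid in list(prepared):
            if sid in settled:
                continue
            trimmed = prepared[sid][start:end]
            if _decision(trimmed.to_numpy()):
                continue
            if n_diffs[sid] < max_diffs:
                n_diffs[sid] += 1
                prepared[sid] = prepared[sid].diff().dropna()
                logs[sid].append(f"diff:{n_diffs[sid]}")
                changed = True
            elif roles[sid] == "growth" or config.on_still_nonstationary == "keep":
                warnings.warn(f"{sid}: still nonstationary after differencing; kept")
                logs[sid].append("nonstationary:kept")
                settled.add(sid)
            else:
                warnings.warn(f"{sid}: still nonstationary after differencing; dropped")
                logs[sid].append("dropped")
                del prepared[sid]
                changed = True
        if not changed:
            break

    start = max(v.index[0] for v in prepared.values())
    end = min(v.index[-1] for v in prepared.values())
    window = pd.period_range(start, end, freq="Q")

    cols: dict[str, np.ndarray] = {}
    for sid, vals in prepared.items():
        trimmed = vals[start:end]
        if len(trimmed) != len(window):
            raise ValueError(f"{sid}: gaps inside the common window")
        cols[sid] = standardize(trimmed.to_numpy())
        logs[sid].append("standardize")

    growth_id = raw.growth.series_id
    order = [s.series_id for s in raw.series if s.series_id in cols and s.series_id != growth_id]
    X = pd.DataFrame({sid: cols[sid] for sid in order}, index=window)
    Y = pd.Series(cols[growth_id], index=window, name=growth_id)
    return StandardizedPanel(quarters=window, X=X, Y=Y, transform_log=logs)


class PanelPreprocessor:
    """Estimator-style wrapper around :func:`build_panel`.

    ``fit_transform(raw)`` returns the :class:`StandardizedPanel`; the
    per-series transform log is stored as ``transform_log_``.
    """

    def __init__(self, adf_max_lag: int = 4, adf_variant: str = "both",
                 on_still_nonstationary: str = "drop"):
        self.adf_max_lag = adf_max_lag
        self.adf_variant = adf_variant
        self.on_still_nonstationary = on_still_nonstationary

    def get_params(self, deep: bool = True) -> dict:
        return {
            "adf_max_lag": self.adf_max_lag,
            "adf_variant": self.adf_variant,
            "on_still_nonstationary": self.on_still_nonstationary,
        }

    def set_params(self, **params) -> "PanelPreprocessor":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, raw: RawPanel) -> "PanelPreprocessor":
        self.panel_ = build_panel(raw, self._config())
        self.transform_log_ = self.panel_.transform_log
        return self

    def fit_transform(self, raw: RawPanel) -> StandardizedPanel:
        return self.fit(raw).panel_

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            adf_max_lag=self.adf_max_lag,
            adf_variant=self.adf_variant,
            on_still_nonstationary=self.on_still_nonstationary,  # type: ignore[arg-type]
        )
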