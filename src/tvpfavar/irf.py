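"""Time-varying impulse responses to a growth shock.

For each origin date t, the VAR coefficients and loadings are frozen at
their smoothed values ("local" impulse responses, the standard construction
for time-varying-parameter VARs).  The structural shock is identified
recursively: a lower-triangular Cholesky factor of Q_t under the ordering
(F_1..F_l, Y) with growth last, so the one-standard-deviation growth shock
is orthogonal to contemporaneous factor innovations.  The response of an
observed indicator is its time-t loading applied to the (Y, F) state
response at each horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IrfArray",
    "companion",
    "structural_impact",
    "irf_states",
    "irf_observables",
    "irf_surface",
]


@dataclass
class IrfArray:
    """Impulse-response surface indexed by (origin time, horizon, target).

    ``values`` has shape (T, H+1, n_targets), in units of standardized
    target per one-standard-deviation growth shock.
    """

    origin_times: pd.PeriodIndex | np.ndarray
    horizons: np.ndarray
    targets: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (origin, horizon, target)."""
        T, H1, K = self.values.shape
        origins = np.repeat(np.asarray(self.origin_times).astype(str), H1 * K)
        horizons = np.tile(np.repeat(self.horizons, K), T)
        targets = np.tile(np.array(self.targets), T * H1)
        return pd.DataFrame(
            {
                "origin": origins,
                "horizon": horizons,
                "target": targets,
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def companion(beta_t: np.ndarray, p: int, k: int) -> np.ndarray:
    """Companion matrix (kp x kp) of the VAR(p) coefficient matrix ``beta_t``.

    ``beta_t`` is the (m, k) stacked matrix with intercept row first and the
    lag-j blocks stored transposed (row block j holds B_j', one column per
    equation), as produced by :meth:`TVPFAVAR.beta_matrix`.
    """
    m = 1 + k * p
    if beta_t.shape != (m, k):
        raise ValueError(f"beta_t must have shape ({m}, {k}), got {beta_t.shape}")
    A = np.zeros((k * p, k * p))
    for j in range(p):
        A[:k, j * k : (j + 1) * k] = beta_t[1 + j * k : 1 + (j + 1) * k, :].T
    if p > 1:
        A[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    return A


def structural_impact(
    Q_t: np.ndarray, shock_index: int = 0, ordering: np.ndarray | None = None
) -> np.ndarray:
    """Impact vector of a one-sd structural shock under recursive identification.

    ``Q_t`` is the reduced-form innovation covariance in z-ordering (Y
    first, factors after).  ``ordering`` gives the causal ordering as
    indices into z; default places the factors first and growth (index 0)
    last.  The returned vector is expressed back in z-ordering.
    """
    Q_t = np.asarray(Q_t, dtype=float)
    k = Q_t.shape[0]
    if ordering is None:
        ordering = np.array(list(range(1, k)) + [0])
    ordering = np.asarray(ordering)
    perm = Q_t[np.ix_(ordering, ordering)]
    try:
        L = np.linalg.cholesky(perm)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"Q_t is not positive definite: {exc}") from exc
    pos = int(np.where(ordering == shock_index)[0][0])
    impact_perm = L[:, pos]
    impact = np.empty(k)
    impact[ordering] = impact_perm
    return impact


def irf_states(
    beta_t: np.ndarray,
    Q_t: np.ndarray,
    horizon: int,
    shock_index: int = 0,
    p: int | None = None,
    ordering: np.ndarray | None = None,
) -> np.ndarray:
    """Responses of the state z = (Y, F) over horizons 0..H, coefficients
    frozen at one origin.

    Horizon-h response = top block of companion**h applied to the structural
    impact.  An unstable companion (spectral radius >= 1) is flagged with a
    warning but responses are still returned.
    """
    k = Q_t.shape[0]
    if p is None:
        p = (beta_t.shape[0] - 1) // k
    A = companion(beta_t, p, k)
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if radius >= 1.0:
        warnings.warn(f"unstable companion matrix (spectral radius {radius:.3f})")
    impact = structural_impact(Q_t, shock_index, ordering)
    resp = np.empty((horizon + 1, k))
    vec = np.zeros(k * p)
    vec[:k] = impact
    resp[0] = impact
    for h in range(1, horizon + 1):
        vec = A @ vec
        resp[h] = vec[:k]
    return resp


def irf_observables(
    model,
    t: int,
    horizon: int = 12,
    targets: list[str] | None = None,
    shock_index: int = 0,
    smoothed: bool = True,
) -> np.ndarray:
    """Responses of observed indicators at origin ``t``: the time-t loading
    row applied to the state response at each horizon.  Returns
    (H+1, n_targets)."""
    names = model.target_names_
    if targets is None:
        targets = names
    missing = [x for x in targets if x not in names]
    if missing:
        raise KeyError(f"unknown target series: {missing}")
    idx = [names.index(x) for x in targets]
    beta_t = model.beta_matrix(t, smoothed=smoothed)
    Q_t = (model.Q_smoothed_ if smoothed else model.Q_filtered_)[t]
    lam_t = (model.lambda_smoothed_ if smoothed else model.lambda_filtered_)[t][idx]
    state_resp = irf_states(beta_t, Q_t, horizon, shock_index, p=model.lags)
    return state_resp @ lam_t.T


def irf_surface(model, horizon: int = 12, targets: list[str] | None = None,
                shock_index: int = 0) -> IrfArray:
    """Impulse responses at every origin date: the (t, h, target) surface."""
    if targets is None:
        targets = model.target_names_
    T = model.T_
    values = np.empty((T, horizon + 1, len(targets)))
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for t in range(T):
            values[t] = irf_observables(model, t, horizon, targets, shock_index)
    origins = getattr(model, "origin_times_", None)
    if origins is None:
        origins = np.arange(T)
    return IrfArray(
        origin_times=origins,
        horizons=np.arange(horizon + 1),
        targets=list(targets),
        values=values,
    )
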