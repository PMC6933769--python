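"""Principal-component factor extraction and regressor assembly.

The two-step estimation strategy replaces the latent factors by full-sample
principal components of the standardized observation block, then stacks the
growth series in front of them to form the filter regressor
``z_t = (Y_t, F_t)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .panel import StandardizedPanel

__all__ = ["FactorSet", "FactorExtractor", "extract_factors", "build_regressors"]


@dataclass
class FactorSet:
    """Extracted common factors: unit-variance scores F (T x l), loadings
    (n x l), nonincreasing explained variances, and the applied per-factor
    sign flips."""

    F: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    sign_convention: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.F.shape[1]

    def save(self, scores_path: str | Path, loadings_path: str | Path,
             variance_path: str | Path) -> None:
        pd.DataFrame(self.F, columns=[f"factor{j+1}" for j in range(self.n_factors)]).to_csv(
            scores_path, index=False
        )
        pd.DataFrame(self.loadings, columns=[f"factor{j+1}" for j in range(self.n_factors)]).to_csv(
            loadings_path, index=False
        )
        Path(variance_path).write_text(
            json.dumps(
                {
                    "explained_variance": self.explained_variance.tolist(),
                    "sign_convention": self.sign_convention.tolist(),
                },
                indent=1,
            )
        )


class FactorExtractor(TransformerMixin, BaseEstimator):
    """PCA factor extractor with a reproducible orientation.

    Scores are rescaled to unit sample variance (the scale the filter's
    priors assume) and each factor's sign is fixed so its largest-magnitude
    loading is positive, making downstream impulse responses reproducible.

    Attributes after fit: ``loadings_`` (n x l), ``explained_variance_``,
    ``explained_variance_ratio_``, ``scores_`` (T x l, training scores),
    ``signs_``.
    """

    def __init__(self, n_factors: int = 3):
        self.n_factors = n_factors

    def fit(self, X, y=None) -> "FactorExtractor":
        X = check_array(X, dtype=float)
        T, n = X.shape
        if not 1 <= self.n_factors <= min(T, n):
            raise ValueError(f"n_factors must be in [1, min(T, n)] = [1, {min(T, n)}]")
        pca = PCA(n_components=self.n_factors, svd_solver="full")
        scores = pca.fit_transform(X)
        sd = scores.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("degenerate component with zero variance")
        scores = scores / sd
        # loadings via OLS of X on the unit-variance orthogonal scores
        loadings = X.T @ scores / (T - 1)
        signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(self.n_factors)])
        signs[signs == 0] = 1.0
        self.scores_ = scores * signs
        self.loadings_ = loadings * signs
        self.signs_ = signs
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        self.components_ = pca.components_ * signs[:, None]
        self._score_sd_ = sd
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ (self.components_ / self._score_sd_[:, None]).T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def to_factor_set(self) -> FactorSet:
        check_is_fitted(self, "loadings_")
        return FactorSet(
            F=self.scores_,
            loadings=self.loadings_,
            explained_variance=self.explained_variance_,
            sign_convention=self.signs_,
        )


def extract_factors(panel: StandardizedPanel, l: int) -> FactorSet:
    """Extract ``l`` principal-component factors from the panel's X block
    (growth excluded by construction of the panel)."""
    return FactorExtractor(n_factors=l).fit(panel.X.to_numpy()).to_factor_set()


def build_regressors(panel: StandardizedPanel, factors: FactorSet | None) -> np.ndarray:
    """Stack the regressor path ``Z`` (T x (l+1)), growth first.

    ``factors=None`` degenerates to the growth column alone.
    """
    y = panel.Y.to_numpy(dtype=float)[:, None]
    if factors is None or factors.n_factors == 0:
        return y
    if len(factors.F) != len(y):
        raise ValueError(
            f"factor path length {len(factors.F)} does not match panel length {len(y)}"
        )
    return np.hstack([y, factors.F])
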