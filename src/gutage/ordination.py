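"""Transformation-based PCA for community-style ordination.

Raw PCA on count tables is dominated by abundance scale and double zeros;
the Hellinger transform — the square root of within-sample relative
abundance — makes Euclidean distances, and hence ordinary PCA, appropriate
for sparse community data. This module implements that composition
("transformation-based PCA") with a deterministic component-sign convention
so ordinations are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import FunctionalProfileMatrix, ValidationError


@dataclass
class OrdinationResult:
    """Sample scores and explained-variance fractions of an ordination."""

    sample_scores: np.ndarray          # samples x components
    explained_fraction: np.ndarray     # per-component, non-increasing
    component_count: int

    def __post_init__(self) -> None:
        ef = np.asarray(self.explained_fraction, dtype=float)
        if (np.diff(ef) > 1e-9).any():
            raise ValueError("explained fractions must be non-increasing")
        if ((ef < -1e-12) | (ef > 1 + 1e-9)).any() or ef.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must lie in [0, 1] and sum <= 1")


def hellinger_transform(X) -> np.ndarray:
    """Square root of each sample's relative abundances (rows get unit norm)."""
    if isinstance(X, FunctionalProfileMatrix):
        values, ids = X.values, X.sample_ids
    else:
        values = np.asarray(X, dtype=float)
        ids = [str(i) for i in range(values.shape[0])]
    if (values < 0).any():
        raise ValidationError("Hellinger transform requires non-negative input")
    row_sums = values.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample row(s): {[ids[i] for i in zero[:5]]}")
    return np.sqrt(values / row_sums[:, np.newaxis])


class HellingerPCA(TransformerMixin, BaseEstimator):
    """PCA of the Hellinger-transformed, column-centered profile matrix.

    When ``feature_subset`` is given, the matrix is first restricted to
    those features and the relative abundances are recomputed within the
    subset, so the transform stays a valid composition on the reduced table.
    Component signs are fixed so each component's largest-magnitude feature
    loading is positive.
    """

    def __init__(self, n_components: int = 2,
                 feature_subset: Sequence[str] | None = None):
        self.n_components = n_components
        self.feature_subset = feature_subset

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        if isinstance(X, FunctionalProfileMatrix):
            frame = X.data
        elif isinstance(X, pd.DataFrame):
            frame = X
        else:
            frame = pd.DataFrame(np.asarray(X, dtype=float))
        if self.feature_subset is not None:
            kept = [f for f in self.feature_subset if f in frame.columns]
            if not kept:
                raise ValueError("feature_subset shares no features with X")
            frame = frame.loc[:, kept]
        n_samples, n_feats = frame.shape
        max_rank = min(n_samples - 1, n_feats)
        if not (1 <= self.n_components <= max_rank):
            raise ValueError(
                f"n_components must be in [1, {max_rank}] for this matrix")
        H = hellinger_transform(frame.to_numpy(dtype=float))
        self.mean_ = H.mean(axis=0)
        centered = H - self.mean_
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        # deterministic orientation: dominant loading of each PC positive
        for k in range(Vt.shape[0]):
            j = int(np.argmax(np.abs(Vt[k])))
            if Vt[k, j] < 0:
                Vt[k] *= -1.0
                U[:, k] *= -1.0
        var = s**2
        total = var.sum()
        self.feature_names_ = [str(c) for c in frame.columns]
        self.singular_values_ = s[: self.n_components]
        self.components_ = Vt[: self.n_components]
        self.explained_variance_ratio_ = (
            var[: self.n_components] / total if total > 0
            else np.zeros(self.n_components)
        )
        scores = U[:, : self.n_components] * s[: self.n_components]
        self.scores_ = scores
        return scores

    def transform(self, X):
        if isinstance(X, FunctionalProfileMatrix):
            frame = X.data
        elif isinstance(X, pd.DataFrame):
            frame = X
        else:
            frame = pd.DataFrame(np.asarray(X, dtype=float),
                                 columns=self.feature_names_)
        frame = frame.loc[:, self.feature_names_]
        H = hellinger_transform(frame.to_numpy(dtype=float))
        return (H - self.mean_) @ self.components_.T


def tbpca(X, n_components: int = 2,
          feature_subset: Sequence[str] | None = None) -> OrdinationResult:
    """Transformation-based PCA: Hellinger transform, center, eigendecompose."""
    est = HellingerPCA(n_components=n_components, feature_subset=feature_subset)
    scores = est.fit_transform(X)
    return OrdinationResult(sample_scores=scores,
                            explained_fraction=est.explained_variance_ratio_,
                            component_count=n_components)
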