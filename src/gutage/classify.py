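"""Age-cutoff labeling and linear maximal-margin classification.

A cohort is split into "young" (age <= cutoff) and "old" (age > cutoff)
classes, and a soft-margin linear SVM is fit on the selected features. The
decision-score orientation is fixed so that positive scores mean "old",
which keeps ROC/AUC well-defined when scores are pooled across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .profiles import FunctionalProfileMatrix, SampleRecord

YOUNG = "young"
OLD = "old"


class LabelingError(ValueError):
    """An age cutoff produced an empty class."""


@dataclass
class AgeLabeling:
    """Young/old class assignment induced by an integer age cutoff."""

    cutoff: int
    labels: dict[str, str]  # sample_id -> "young" | "old"

    def for_samples(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.labels[s] for s in sample_ids])


def label_by_cutoff(records: Iterable[SampleRecord], cutoff: int) -> AgeLabeling:
    """Label each sample young (age <= cutoff) or old (age > cutoff).

    Raises LabelingError naming the empty class if the cutoff does not
    produce two non-empty classes.
    """
    labels = {r.sample_id: (YOUNG if r.age <= cutoff else OLD) for r in records}
    if not labels:
        raise LabelingError("no samples to label")
    present = set(labels.values())
    for cls in (YOUNG, OLD):
        if cls not in present:
            raise LabelingError(f"cutoff {cutoff} leaves the {cls!r} class empty")
    return AgeLabeling(cutoff=int(cutoff), labels=labels)


@dataclass
class LinearModel:
    """A fitted linear decision function f(x) = w . x + b over named features."""

    feature_ids: list[str]
    weights: np.ndarray
    intercept: float
    regularization: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.shape[0] != len(self.feature_ids):
            raise ValueError("weights must align with feature_ids")


class LinearMarginClassifier(ClassifierMixin, BaseEstimator):
    """Soft-margin linear SVM with a fixed young/old score orientation.

    Thin wrapper around ``sklearn.svm.SVC(kernel="linear")``. The positive
    decision direction is the "old" class when labels are young/old strings
    (otherwise the larger of the two sorted labels). Optional per-feature
    z-scoring uses training statistics only and is off by default — the
    counts are used as-is.
    """

    def __init__(self, C: float = 1.0, scale: bool = False,
                 max_iter: int = 1_000_000):
        self.C = C
        self.scale = scale
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
        if OLD in classes:
            self.positive_class_ = OLD
        else:
            self.positive_class_ = classes[1]
        self.negative_class_ = classes[classes != self.positive_class_][0]
        y_bin = (y == self.positive_class_).astype(int)
        self.scaler_ = None
        if self.scale:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        # merge identical (row, label) pairs into one weighted sample: the
        # hinge terms add, so the objective is unchanged, and libsvm avoids
        # cycling on duplicate points (common after sparse feature selection)
        stacked = np.column_stack([X, y_bin])
        uniq, counts = np.unique(stacked, axis=0, return_counts=True)
        # the iteration cap bounds runtime on ill-conditioned folds (raw
        # counts span orders of magnitude); typical fits converge well below
        # it, and truncation is deterministic given identical inputs
        self.svc_ = SVC(kernel="linear", C=self.C, max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.svc_.fit(uniq[:, :-1], uniq[:, -1].astype(int),
                          sample_weight=counts.astype(float))
        self.classes_ = np.asarray([self.negative_class_, self.positive_class_])
        self.coef_ = self.svc_.coef_.copy()
        self.intercept_ = self.svc_.intercept_.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self.svc_.decision_function(X)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.positive_class_, self.negative_class_)


def fit_linear(X, y, C: float = 1.0, scale: bool = False) -> LinearModel:
    """Fit the linear SVM and return its explicit (w, b) representation."""
    if isinstance(X, FunctionalProfileMatrix):
        feature_ids, arr = X.feature_ids, X.values
    elif isinstance(X, pd.DataFrame):
        feature_ids, arr = [str(c) for c in X.columns], X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        feature_ids = [f"f{i}" for i in range(arr.shape[1])]
    if scale:
        # fold scaling into (w, b) so decision_score stays a plain dot product
        clf = LinearMarginClassifier(C=C, scale=True).fit(arr, y)
        w = (clf.coef_[0] / clf.scaler_.scale_)
        b = float(clf.intercept_[0] - (clf.scaler_.mean_ / clf.scaler_.scale_)
                  @ clf.coef_[0])
    else:
        clf = LinearMarginClassifier(C=C).fit(arr, y)
        w, b = clf.coef_[0], float(clf.intercept_[0])
    return LinearModel(feature_ids=list(feature_ids), weights=w,
                       intercept=b, regularization=float(C))


def decision_score(model: LinearModel, x) -> float:
    """Score one sample: w . x + b, positive meaning "old".

    ``x`` may be a mapping/Series keyed by feature id (features absent from
    the model are ignored; model features absent from x count as zero) or a
    plain vector already aligned to ``model.feature_ids``.
    """
    if isinstance(x, Mapping):
        x = pd.Series(x)
    if isinstance(x, pd.Series):
        vec = x.reindex(model.feature_ids).fillna(0.0).to_numpy(dtype=float)
    else:
        vec = np.asarray(x, dtype=float).ravel()
        if vec.shape[0] != len(model.feature_ids):
            raise ValueError(
                f"expected vector of length {len(model.feature_ids)}, "
                f"got {vec.shape[0]}"
            )
    return float(model.weights @ vec + model.intercept)
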