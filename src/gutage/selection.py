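"""Discriminative-feature selection for functional profiles.

Three selectors are provided, each available both as a module-level ranking
function and as a scikit-learn style transformer:

* **TF-iDF** — term-frequency x inverse-document-frequency weighting. For
  sample j and feature i with count n_ij,

      tfidf_ij = (n_ij / sum_k n_kj) * log(|D| / m_i)

  where |D| is the number of samples and m_i the number of samples in which
  feature i occurs. It up-weights features that take a large share of a few
  samples' assignments but occur in few samples overall ("accessory"
  features), and ignores class labels entirely.

* **mRMR** — minimum-redundancy maximum-relevance greedy selection on a
  mean +/- sd discretization of the counts, maximizing mutual information
  with the class label while penalizing the average mutual information with
  already-selected features.

* **Grubbs-weighted** — an outlier-driven scheme: each feature's abundance
  vector is screened with Grubbs' single-outlier test; for every training
  sample flagged as an outlier by some feature set, a linear SVM restricted
  to that feature set is trained on the remaining samples, and the features
  earn weight 1 whenever the flagged sample is classified correctly. Features
  are ranked by total weight. Like TF-iDF it prefers rare patterns, but it
  rewards only single-sample outlier structure — which is exactly what makes
  it a useful control for TF-iDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .profiles import FunctionalProfileMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class TfIdfWeights:
    """Per-(sample, feature) TF-iDF weights aligned to a profile matrix."""

    weights: pd.DataFrame
    log_base: float  # e for natural log


@dataclass
class DiscretizedMatrix:
    """Counts discretized to {-1, 0, +1} around each feature's mean +/- t*sd."""

    values: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("discretized entries must lie in {-1, 0, +1}")


@dataclass
class FeatureRanking:
    """Ordered, scored feature list produced by a selector.

    ``trace`` (mRMR only) records the running relevance D(S,c) and redundancy
    R(S) after each greedy step.
    """

    method: str
    features: list[str]
    scores: list[float]
    trace: list[dict] | None = None

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores must be parallel")
        if len(set(self.features)) != len(self.features):
            raise ValueError("ranked features must be unique")


# ---------------------------------------------------------------------------
# TF-iDF


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, FunctionalProfileMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x features array")
    width = len(str(arr.shape[1] - 1)) if arr.shape[1] else 1
    cols = [f"f{i:0{width}d}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def tfidf_weights(X, log_base: float | None = None) -> TfIdfWeights:
    """Compute TF-iDF weights for every (sample, feature) cell.

    TF is the feature's share of its sample's total assignments; iDF is
    log(|D| / m_i) with m_i the number of samples containing the feature.
    Natural log by default (the base rescales scores uniformly and cannot
    change any ranking). Features occurring in every sample get weight 0, as
    do all cells of features occurring nowhere; all-zero sample rows yield
    all-zero weight rows.
    """
    frame = _as_frame(X)
    if frame.shape[0] < 2:
        raise ValueError("TF-iDF needs at least 2 samples (iDF is degenerate)")
    counts = frame.to_numpy(dtype=float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tf = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    m = (counts > 0).sum(axis=0)
    n = counts.shape[0]
    idf = np.zeros(counts.shape[1])
    present = m > 0
    idf[present] = np.log(n / m[present])
    if log_base is not None:
        idf /= np.log(log_base)
    weights = tf * idf[np.newaxis, :]
    return TfIdfWeights(
        weights=pd.DataFrame(weights, index=frame.index, columns=frame.columns),
        log_base=float(log_base) if log_base is not None else float(np.e),
    )


def _top_n(scored: "pd.Series", n: int, method: str,
           trace: list[dict] | None = None) -> FeatureRanking:
    """Top-n by score, descending, lexicographic feature-id tie-break."""
    order = sorted(scored.index, key=lambda f: (-scored[f], str(f)))
    chosen = order[:n]
    return FeatureRanking(method=method,
                          features=[str(f) for f in chosen],
                          scores=[float(scored[f]) for f in chosen],
                          trace=trace)


def tfidf_rank(X, n: int, log_base: float | None = None,
               aggregate: str = "max") -> FeatureRanking:
    """Rank features by their TF-iDF weight aggregated over training samples.

    The per-feature score is the maximum (default) or the sum of the
    feature's TF-iDF weights across samples; "max" matches the selection of
    features with a high share in few samples. Only features with a nonzero
    weight somewhere are ranked; if fewer than ``n`` qualify, all of them are
    returned. Class labels are never consulted.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if aggregate not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    w = tfidf_weights(X, log_base=log_base).weights
    scores = w.max(axis=0) if aggregate == "max" else w.sum(axis=0)
    scores = scores[scores > 0]
    return _top_n(scores, n, "tfidf")


# ---------------------------------------------------------------------------
# Discretization and mutual information


def discretize(X, t: float = 1.0) -> DiscretizedMatrix:
    """Discretize counts feature-wise to {-1, 0, +1} at mean +/- t * sd.

    Uses the sample standard deviation (n-1 denominator). Constant columns
    (sd = 0) map to all zeros.
    """
    if t <= 0:
        raise ValueError(f"threshold must be positive, got {t}")
    frame = _as_frame(X)
    counts = frame.to_numpy(dtype=float)
    mu = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if counts.shape[0] > 1 else np.zeros(counts.shape[1])
    hi = mu + t * sd
    lo = mu - t * sd
    out = np.zeros(counts.shape, dtype=np.int8)
    nondegenerate = sd > 0
    out[:, nondegenerate] = (
        (counts[:, nondegenerate] > hi[nondegenerate]).astype(np.int8)
        - (counts[:, nondegenerate] < lo[nondegenerate]).astype(np.int8)
    )
    return DiscretizedMatrix(values=out, threshold=float(t))


def _codes(v: np.ndarray) -> np.ndarray:
    """Map arbitrary discrete labels to consecutive integer codes."""
    _, codes = np.unique(np.asarray(v), return_inverse=True)
    return codes


def mutual_information(a, b) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    Estimated from the empirical joint distribution with a base-2 logarithm;
    I(a; a) equals the empirical entropy of a.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("vectors must have equal length")
    if a.shape[0] == 0:
        raise ValueError("vectors must be non-empty")
    ca, cb = _codes(a), _codes(b)
    joint = np.zeros((ca.max() + 1, cb.max() + 1))
    np.add.at(joint, (ca, cb), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())


def _mi_vector(y_codes: np.ndarray, n_y: int, Z: np.ndarray) -> np.ndarray:
    """MI (bits) of one discrete vector against every column of Z in {-1,0,1}."""
    n = Z.shape[0]
    Y = np.zeros((n, n_y))
    Y[np.arange(n), y_codes] = 1.0
    joint = np.stack([Y.T @ (Z == v) for v in (-1, 0, 1)], axis=1) / n  # ky x 3 x f
    pz = joint.sum(axis=0)                       # 3 x f
    py = joint.sum(axis=1)                       # ky x f
    denom = py[:, np.newaxis, :] * pz[np.newaxis, :, :]
    nz = joint > 0
    term = np.zeros_like(joint)
    term[nz] = joint[nz] * np.log2(joint[nz] / denom[nz])
    return np.maximum(term.sum(axis=(0, 1)), 0.0)


def mrmr_select(X, labels, n: int, t: float = 1.0,
                combination: str = "difference") -> FeatureRanking:
    """Greedy mRMR selection on the discretized profile matrix.

    The first feature maximizes relevance I(x_i; c); each subsequent feature
    maximizes, over candidates x_i,

        difference:  I(x_i; c) - (1/|S|) * sum_{x_j in S} I(x_i; x_j)
        quotient:    I(x_i; c) / ((1/|S|) * sum_{x_j in S} I(x_i; x_j))

    with S the already-selected set. Ties break lexicographically on feature
    identifier. The trace records the running mean relevance D(S, c) and mean
    pairwise redundancy R(S) (diagonal entropies included) after each step.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if combination not in ("difference", "quotient"):
        raise ValueError(f"unknown combination {combination!r}")
    frame = _as_frame(X)
    y = np.asarray(labels)
    if y.shape[0] != frame.shape[0]:
        raise ValueError("labels must align with samples")
    if len(np.unique(y)) < 2:
        raise ValueError("mRMR needs two classes in the labels")
    disc = discretize(frame, t=t).values
    features = [str(f) for f in frame.columns]
    # lexicographic candidate order makes argmax ties deterministic
    lex = sorted(range(len(features)), key=lambda i: features[i])
    y_codes = _codes(y)
    relevance = _mi_vector(y_codes, int(y_codes.max()) + 1, disc)

    selected: list[int] = []
    scores: list[float] = []
    trace: list[dict] = []
    red_sum = np.zeros(len(features))     # sum over selected of I(x_i; x_j)
    pair_sum = 0.0                        # off-diagonal pair MI sum (ordered pairs)
    diag_sum = 0.0                        # sum of selected self-informations
    n_pick = min(n, len(features))
    for _ in range(n_pick):
        best_i, best_score = -1, -np.inf
        k = len(selected)
        for i in lex:
            if i in selected:
                continue
            if k == 0:
                score = relevance[i]
            elif combination == "difference":
                score = relevance[i] - red_sum[i] / k
            else:
                mean_red = red_sum[i] / k
                score = relevance[i] / mean_red if mean_red > 0 else np.inf
            if score > best_score:
                best_i, best_score = i, score
        sel_col = disc[:, best_i]
        pair_sum += 2.0 * red_sum[best_i]
        diag_sum += mutual_information(sel_col, sel_col)
        selected.append(best_i)
        scores.append(float(best_score))
        new_mi = _mi_vector(_codes(sel_col), int(_codes(sel_col).max()) + 1, disc)
        red_sum += new_mi
        s = len(selected)
        trace.append({
            "feature": features[best_i],
            "relevance_D": float(relevance[selected].mean()),
            "redundancy_R": float((pair_sum + diag_sum) / (s * s)),
        })
    return FeatureRanking(method="mrmr",
                          features=[features[i] for i in selected],
                          scores=scores, trace=trace)


# ---------------------------------------------------------------------------
# Grubbs' test


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution formula."""
    if n < 3:
        raise ValueError("Grubbs' test needs at least 3 observations")
    t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2)))


def grubbs_statistic(values, alpha: float = 0.05) -> tuple[float, int, bool]:
    """Grubbs' single-outlier statistic G = max |v_i - mean| / sd.

    Returns (G, index of the most deviant observation, outlier flag at the
    two-sided significance ``alpha``). Sample sd (n-1 denominator); a
    constant vector has G defined as 0 and no outlier.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.shape[0] < 3:
        raise ValueError("Grubbs' test needs at least 3 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        return 0.0, 0, False
    dev = np.abs(v - v.mean()) / sd
    idx = int(np.argmax(dev))
    g = float(dev[idx])
    return g, idx, g > grubbs_critical_value(v.shape[0], alpha)


def grubbs_weighted_select(X, labels, n: int, alpha: float = 0.05,
                           C: float = 1.0,
                           max_iter: int = 20_000) -> FeatureRanking:
    """Rank features by how often their outlier calls are classifiable.

    For each feature, Grubbs' test flags at most one training sample as an
    outlier. Each flagged sample s, with flagging feature set P_s, is then
    classified by a linear SVM trained on the remaining training samples
    restricted to P_s; every feature in P_s gains weight 1 when the
    prediction is correct. The top-n features by accumulated weight are
    returned (never-flagged features have weight 0 and are not ranked).

    The internal per-flagged-sample fits only contribute a correct/incorrect
    vote, so their solver runs under a modest iteration bound (``max_iter``)
    that keeps the scheme's cost manageable on wide tables; the bound is
    deterministic given identical inputs.
    """
    from .classify import LinearMarginClassifier

    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    frame = _as_frame(X)
    y = np.asarray(labels)
    if frame.shape[0] < 4:
        raise ValueError("need at least 4 training samples")
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes in the labels")
    counts = frame.to_numpy(dtype=float)
    n_samp, n_feat = counts.shape
    mu = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    ok = sd > 0
    dev = np.zeros_like(counts)
    dev[:, ok] = np.abs(counts[:, ok] - mu[ok]) / sd[ok]
    g = dev.max(axis=0)
    argmax = dev.argmax(axis=0)
    crit = grubbs_critical_value(n_samp, alpha)
    flagged_features = np.flatnonzero(ok & (g > crit))
    if flagged_features.size == 0:
        logger.warning("Grubbs-weighted selection: no sample flagged by any feature")
        return FeatureRanking(method="grubbs", features=[], scores=[])

    by_sample: dict[int, list[int]] = {}
    for f in flagged_features:
        by_sample.setdefault(int(argmax[f]), []).append(int(f))

    weights = np.zeros(n_feat)
    features = [str(f) for f in frame.columns]
    for s, fs in by_sample.items():
        train_mask = np.ones(n_samp, dtype=bool)
        train_mask[s] = False
        y_train = y[train_mask]
        if len(np.unique(y_train)) < 2:
            continue
        clf = LinearMarginClassifier(C=C, max_iter=max_iter)
        clf.fit(counts[np.ix_(train_mask, fs)], y_train)
        pred = clf.predict(counts[s, fs].reshape(1, -1))[0]
        if pred == y[s]:
            weights[fs] += 1.0
    scored = pd.Series(weights, index=features)
    scored = scored[scored > 0]
    if scored.empty:
        logger.warning("Grubbs-weighted selection: no flagged sample classified "
                       "correctly; empty ranking")
        return FeatureRanking(method="grubbs", features=[], scores=[])
    return _top_n(scored, n, "grubbs")


# ---------------------------------------------------------------------------
# scikit-learn transformer facades


class _RankingSelector(SelectorMixin, BaseEstimator):
    """Shared fit/transform plumbing for ranking-based selectors."""

    def _rank(self, frame: pd.DataFrame, y) -> FeatureRanking:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None):
        frame = _as_frame(X)
        self.feature_names_in_ = np.asarray([str(c) for c in frame.columns])
        self.n_features_in_ = frame.shape[1]
        self.ranking_ = self._rank(frame, y)
        chosen = set(self.ranking_.features)
        self.support_ = np.asarray([f in chosen for f in self.feature_names_in_])
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "support_")


class TfidfSelector(_RankingSelector):
    """Select the top-n features by aggregated TF-iDF weight (unsupervised)."""

    def __init__(self, n_features: int = 10, log_base: float | None = None,
                 aggregate: str = "max"):
        self.n_features = n_features
        self.log_base = log_base
        self.aggregate = aggregate

    def _rank(self, frame, y):
        return tfidf_rank(frame, self.n_features, log_base=self.log_base,
                          aggregate=self.aggregate)


class MrmrSelector(_RankingSelector):
    """Select n features by greedy minimum-redundancy maximum-relevance."""

    def __init__(self, n_features: int = 10, threshold: float = 1.0,
                 combination: str = "difference"):
        self.n_features = n_features
        self.threshold = threshold
        self.combination = combination

    def _rank(self, frame, y):
        if y is None:
            raise ValueError("MrmrSelector requires class labels")
        return mrmr_select(frame, y, self.n_features, t=self.threshold,
                           combination=self.combination)


class GrubbsWeightedSelector(_RankingSelector):
    """Select n features by the Grubbs-outlier classification-weight scheme."""

    def __init__(self, n_features: int = 10, alpha: float = 0.05, C: float = 1.0):
        self.n_features = n_features
        self.alpha = alpha
        self.C = C

    def _rank(self, frame, y):
        if y is None:
            raise ValueError("GrubbsWeightedSelector requires class labels")
        return grubbs_weighted_select(frame, y, self.n_features,
                                      alpha=self.alpha, C=self.C)
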