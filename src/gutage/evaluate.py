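"""Leave-one-out evaluation with in-fold selection, and age-cutoff sweeps.

The evaluation protocol mirrors how novel metagenomes would be classified:
random subsets of the cohort are drawn; within each subset a leave-one-out
cross-validation runs the feature selector *on the training samples of every
fold* (no selection leakage), fits the linear SVM on the selected features,
and scores the left-out sample. Per-run AUC is computed on the pooled
left-out decision scores; mean AUC, a t-based 95% confidence interval and
mean accuracy are reported across runs. Sweeping the young/old age cutoff
year by year shows where along the lifespan the functional profiles are
most discriminable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import AgeLabeling, LinearMarginClassifier, OLD, label_by_cutoff, LabelingError
from .profiles import FunctionalProfileMatrix, SampleRecord
from .selection import grubbs_weighted_select, mrmr_select, tfidf_rank

logger = logging.getLogger(__name__)

SELECTORS = ("tfidf", "mrmr", "grubbs")


def auc(scores, labels, positive: str = OLD) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formula.

    Equals the probability that a uniformly drawn positive ("old") sample
    scores above a uniformly drawn negative one, with ties half-credited.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must align")
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _run_selector(selector: str, X_train: pd.DataFrame, y_train: np.ndarray,
                  n_features: int, selector_params: dict) -> list[str]:
    params = dict(selector_params or {})
    if selector == "tfidf":
        return tfidf_rank(X_train, n_features,
                          log_base=params.get("log_base"),
                          aggregate=params.get("aggregate", "max")).features
    if selector == "mrmr":
        return mrmr_select(X_train, y_train, n_features,
                           t=params.get("threshold", 1.0),
                           combination=params.get("combination", "difference")).features
    if selector == "grubbs":
        return grubbs_weighted_select(X_train, y_train, n_features,
                                      alpha=params.get("alpha", 0.05),
                                      C=params.get("C", 1.0)).features
    raise ValueError(f"unknown selector {selector!r}; expected one of {SELECTORS}")


@dataclass
class RunResult:
    """One leave-one-out pass over one random subset."""

    subset_sample_ids: list[str]
    per_sample: list[tuple[str, str, float, str]]  # (id, truth, score, predicted)
    auc: float
    accuracy: float
    selected_feature_log: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if not (np.isnan(self.auc) or 0.0 <= self.auc <= 1.0):
            raise ValueError("auc outside [0, 1]")
        if not (np.isnan(self.accuracy) or 0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy outside [0, 1]")


def loo_run(X: FunctionalProfileMatrix, labeling: AgeLabeling,
            selector: str = "tfidf", n_features: int = 10,
            C: float = 1.0, scale: bool = False,
            selector_params: dict | None = None,
            sample_ids: Sequence[str] | None = None) -> RunResult:
    """Leave-one-out cross-validation with per-fold feature selection.

    For every sample: the selector sees only the remaining samples, the SVM
    is fit on those samples restricted to the selected features, and the
    left-out sample's decision score and prediction are recorded. Folds
    whose training set loses a class, or for which the selector returns no
    features, are skipped with a warning and excluded from the accuracy
    denominator. AUC is computed on the pooled left-out scores.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    ids = list(sample_ids) if sample_ids is not None else X.sample_ids
    frame = X.data.loc[ids]
    y = labeling.for_samples(ids)
    if len(np.unique(y)) < 2:
        raise ValueError("subset must contain both classes")
    per_sample: list[tuple[str, str, float, str]] = []
    feature_log: list[tuple[str, list[str]]] = []
    for i, sid in enumerate(ids):
        mask = np.ones(len(ids), dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %s skipped: training set lost a class", sid)
            continue
        X_train = frame.iloc[mask]
        chosen = _run_selector(selector, X_train, y_train, n_features,
                               selector_params or {})
        if not chosen:
            logger.warning("fold %s skipped: selector returned no features", sid)
            continue
        if len(chosen) < n_features:
            logger.info("fold %s: only %d/%d features available",
                        sid, len(chosen), n_features)
        clf = LinearMarginClassifier(C=C, scale=scale)
        clf.fit(X_train.loc[:, chosen].to_numpy(dtype=float), y_train)
        x_test = frame.loc[[sid], chosen].to_numpy(dtype=float)
        score = float(clf.decision_function(x_test)[0])
        pred = str(clf.predict(x_test)[0])
        per_sample.append((sid, str(y[i]), score, pred))
        feature_log.append((sid, list(chosen)))
    if not per_sample:
        raise ValueError("all folds were skipped; cannot evaluate")
    truths = np.asarray([p[1] for p in per_sample])
    scores = np.asarray([p[2] for p in per_sample])
    preds = np.asarray([p[3] for p in per_sample])
    run_auc = auc(scores, truths) if len(np.unique(truths)) == 2 else float("nan")
    accuracy = float((preds == truths).mean())
    return RunResult(subset_sample_ids=ids, per_sample=per_sample,
                     auc=run_auc, accuracy=accuracy,
                     selected_feature_log=feature_log)


@dataclass
class SweepRow:
    """Aggregated subset-experiment result at one age cutoff."""

    cutoff: int
    selector: str
    n_features: int
    n_runs: int
    subset_size: int
    mean_auc: float
    ci_low: float
    ci_high: float
    mean_accuracy: float
    run_aucs: list[float] = field(default_factory=list)
    selection_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_auc + 1e-12
                and self.mean_auc - 1e-12 <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean AUC")


def _t_ci(values: np.ndarray) -> tuple[float, float]:
    n = values.shape[0]
    mean = float(values.mean())
    if n < 2:
        return mean, mean
    half = float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))
    return mean - half, mean + half


def subset_experiment(X: FunctionalProfileMatrix,
                      records: Iterable[SampleRecord],
                      cutoff: int,
                      selector: str = "tfidf",
                      n_features: int = 10,
                      n_runs: int = 20,
                      subset_size: int = 40,
                      seed: int | np.random.SeedSequence = 0,
                      C: float = 1.0,
                      scale: bool = False,
                      selector_params: dict | None = None) -> SweepRow:
    """Repeat leave-one-out evaluation over random subsets at one cutoff.

    Subsets of ``subset_size`` samples are drawn uniformly without
    replacement, freshly per run from a seeded generator (a draw lacking one
    of the classes is redrawn). Reports mean AUC, its t-based 95% confidence
    interval across runs, mean accuracy, and the per-feature selection rate
    pooled over all folds of all runs.
    """
    records = list(records)
    ids = X.sample_ids
    if subset_size > len(ids):
        raise ValueError(f"subset_size {subset_size} exceeds cohort size {len(ids)}")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    labeling = label_by_cutoff([r for r in records if r.sample_id in set(ids)],
                               cutoff)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    aucs, accs = [], []
    pick_counts: dict[str, int] = {}
    total_folds = 0
    for _ in range(n_runs):
        for _attempt in range(100):
            subset = [ids[k] for k in rng.choice(len(ids), size=subset_size,
                                                 replace=False)]
            if len({labeling.labels[s] for s in subset}) == 2:
                break
        else:
            raise ValueError("could not draw a subset containing both classes")
        run = loo_run(X, labeling, selector=selector, n_features=n_features,
                      C=C, scale=scale, selector_params=selector_params,
                      sample_ids=subset)
        aucs.append(run.auc)
        accs.append(run.accuracy)
        for _sid, feats in run.selected_feature_log:
            total_folds += 1
            for f in feats:
                pick_counts[f] = pick_counts.get(f, 0) + 1
    aucs_arr = np.asarray(aucs, dtype=float)
    ci_low, ci_high = _t_ci(aucs_arr)
    rates = {f: c / total_folds for f, c in sorted(pick_counts.items())}
    return SweepRow(cutoff=int(cutoff), selector=selector,
                    n_features=n_features, n_runs=n_runs,
                    subset_size=subset_size,
                    mean_auc=float(aucs_arr.mean()),
                    ci_low=ci_low, ci_high=ci_high,
                    mean_accuracy=float(np.mean(accs)),
                    run_aucs=[float(a) for a in aucs],
                    selection_rate=rates)


def permutation_null_experiment(X: FunctionalProfileMatrix,
                                records: Iterable[SampleRecord],
                                cutoff: int,
                                selector: str = "tfidf",
                                n_features: int = 10,
                                n_runs: int = 20,
                                subset_size: int = 40,
                                seed: int | np.random.SeedSequence = 0,
                                C: float = 1.0,
                                scale: bool = False,
                                selector_params: dict | None = None
                                ) -> SweepRow:
    """Permutation-null baseline for subset_experiment at one cutoff.

    Each run shuffles the hosts' ages across samples with its own derived
    seed before drawing the subset, so the mean AUC estimates the true
    permutation null rather than the residual chance association of a
    single fixed permutation.
    """
    from .simulate import permute_ages

    records = list(records)
    ids = X.sample_ids
    if subset_size > len(ids):
        raise ValueError(f"subset_size {subset_size} exceeds cohort size {len(ids)}")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_runs)
    rng = np.random.default_rng(ss)
    aucs, accs = [], []
    for child in children:
        perm_seed = int(child.generate_state(1)[0] % (2**31))
        permuted = permute_ages(records, seed=perm_seed)
        labeling = label_by_cutoff(permuted, cutoff)
        for _attempt in range(100):
            subset = [ids[k] for k in rng.choice(len(ids), size=subset_size,
                                                 replace=False)]
            if len({labeling.labels[s] for s in subset}) == 2:
                break
        else:
            raise ValueError("could not draw a subset containing both classes")
        run = loo_run(X, labeling, selector=selector, n_features=n_features,
                      C=C, scale=scale, selector_params=selector_params,
                      sample_ids=subset)
        aucs.append(run.auc)
        accs.append(run.accuracy)
    aucs_arr = np.asarray(aucs, dtype=float)
    ci_low, ci_high = _t_ci(aucs_arr)
    return SweepRow(cutoff=int(cutoff), selector=selector,
                    n_features=n_features, n_runs=n_runs,
                    subset_size=subset_size,
                    mean_auc=float(aucs_arr.mean()),
                    ci_low=ci_low, ci_high=ci_high,
                    mean_accuracy=float(np.mean(accs)))


@dataclass
class SweepReport:
    """Per-cutoff aggregation of the repeated subset experiments."""

    rows: list[SweepRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cutoff": r.cutoff,
                    "selector": r.selector,
                    "n_features": r.n_features,
                    "n_runs": r.n_runs,
                    "subset_size": r.subset_size,
                    "mean_auc": r.mean_auc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "mean_accuracy": r.mean_accuracy,
                }
                for r in self.rows
            ]
        )

    def argmax_cutoff(self) -> int:
        if not self.rows:
            raise ValueError("empty sweep report")
        best = max(self.rows, key=lambda r: (r.mean_auc, -r.cutoff))
        return best.cutoff

    def write_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            frame = self.to_frame()
            fh.write("\t".join(frame.columns) + "\n")
            for _, row in frame.iterrows():
                cells = [f"{v:.6f}" if isinstance(v, float) else str(v)
                         for v in row.tolist()]
                fh.write("\t".join(cells) + "\n")


def cutoff_sweep(X: FunctionalProfileMatrix,
                 records: Iterable[SampleRecord],
                 cutoffs: Sequence[int],
                 selector: str = "tfidf",
                 n_features: int = 10,
                 n_runs: int = 20,
                 subset_size: int = 40,
                 seed: int = 0,
                 C: float = 1.0,
                 scale: bool = False,
                 selector_params: dict | None = None) -> SweepReport:
    """Run subset_experiment at each age cutoff with derived per-cutoff seeds.

    Cutoffs are evaluated independently; each gets a child seed derived
    deterministically from the master seed and the cutoff value, so adding
    or removing cutoffs does not perturb the others. Cutoffs that leave a
    class empty are skipped with a warning.
    """
    rows = []
    for cutoff in cutoffs:
        child = np.random.SeedSequence([int(seed), int(cutoff)])
        try:
            rows.append(subset_experiment(
                X, records, cutoff, selector=selector, n_features=n_features,
                n_runs=n_runs, subset_size=subset_size, seed=child, C=C,
                scale=scale, selector_params=selector_params))
        except LabelingError as exc:
            logger.warning("cutoff %d skipped: %s", cutoff, exc)
    return SweepReport(rows=rows)
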