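"""Two-class metrics, k-fold cross-validation, and the 70/15/15 split.

Metrics follow the standard confusion-count definitions:

    accuracy    = (tp + tn) / (tp + tn + fp + fn)
    precision   = tp / (tp + fp)
    recall      = tp / (tp + fn)          (sensitivity)
    specificity = tn / (tn + fp)
    F1          = 2 * precision * recall / (precision + recall)

A zero denominator makes the metric undefined; it is reported as ``None``
(never an exception, never silently 0) and fold means are taken over the
folds where the metric is defined, with the defined-fold count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

from .core import TUMOR, FeatureTable

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SplitPlan",
    "CVResult",
    "classification_metrics",
    "kfold_cv",
    "train_val_test_split",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Metric values in [0, 1]; ``None`` flags an undefined (0/0) metric."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "MetricsReport":
        def ratio(num: int, den: int) -> float | None:
            return num / den if den > 0 else None

        precision = ratio(c.tp, c.tp + c.fp)
        recall = ratio(c.tp, c.tp + c.fn)
        if precision is None or recall is None or precision + recall == 0:
            f1 = None
        else:
            f1 = 2.0 * precision * recall / (precision + recall)
        return cls(
            accuracy=ratio(c.tp + c.tn, c.total),
            precision=precision,
            recall=recall,
            specificity=ratio(c.tn, c.tn + c.fp),
            f1=f1,
        )


def classification_metrics(labels: np.ndarray, predictions: np.ndarray,
                           positive_class=TUMOR) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and the five standard metrics for two-class labels."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if np.unique(labels).size > 2:
        raise ValueError("labels must come from at most two classes")
    pos_true = labels == positive_class
    pos_pred = predictions == positive_class
    counts = ConfusionCounts(
        tp=int(np.sum(pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )
    return counts, MetricsReport.from_counts(counts)


@dataclass
class CVResult:
    fold_counts: list[ConfusionCounts]
    fold_reports: list[MetricsReport]
    mean_metrics: dict
    n_defined: dict

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_metrics,
            "n_defined": self.n_defined,
            "folds": [r.to_dict() for r in self.fold_reports],
        }


def _shuffled_folds(n: int, k: int, seed: int, labels: np.ndarray | None = None,
                    stratified: bool = False) -> list[np.ndarray]:
    """Seeded shuffle then k near-equal contiguous folds (sizes differ <= 1)."""
    rng = np.random.default_rng(seed)
    if stratified and labels is not None:
        # round-robin assignment within each shuffled class
        order = rng.permutation(n)
        folds: list[list[int]] = [[] for _ in range(k)]
        slot = 0
        for cls in np.unique(labels):
            for idx in order[np.isin(order, np.where(labels == cls)[0])]:
                folds[slot % k].append(int(idx))
                slot += 1
        return [np.array(sorted(f)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def kfold_cv(table: FeatureTable, classifier, k: int = 10, seed: int = 0,
             positive_class=TUMOR, stratified: bool = False) -> CVResult:
    """Seeded k-fold cross-validation of a scikit-learn style classifier.

    Folds are plain shuffled partitions by default (``stratified=True`` for
    class-balanced folds).  Returns per-fold counts/metrics and the mean of
    each metric over folds where it is defined.
    """
    n = table.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    folds = _shuffled_folds(n, k, seed, table.labels, stratified)
    all_idx = np.arange(n)
    fold_counts: list[ConfusionCounts] = []
    fold_reports: list[MetricsReport] = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        clf = clone(classifier)
        clf.fit(table.X[train_idx], table.labels[train_idx])
        pred = clf.predict(table.X[test_idx])
        counts, report = classification_metrics(table.labels[test_idx], pred,
                                                positive_class)
        fold_counts.append(counts)
        fold_reports.append(report)
    mean_metrics: dict = {}
    n_defined: dict = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in fold_reports if getattr(r, name) is not None]
        n_defined[name] = len(vals)
        mean_metrics[name] = float(np.mean(vals)) if vals else None
    return CVResult(fold_counts, fold_reports, mean_metrics, n_defined)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation/test index sets covering all samples."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def train_val_test_split(n: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                         seed: int = 0) -> SplitPlan:
    """Seeded shuffle, then contiguous slices of rounded sizes; the training
    set absorbs the rounding remainder."""
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("fractions leave a negative split size")
    return SplitPlan(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train:n_train + n_val]),
        test=np.sort(perm[n_train + n_val:]),
        fractions=tuple(fractions),
        seed=seed,
    )
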