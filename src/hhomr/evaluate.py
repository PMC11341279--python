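"""Fold construction and classification metrics.

AUC is computed by the rank (Mann-Whitney) formula with average ranks, which
gives every tied positive-negative pair weight 0.5 — identical to the
brute-force pairwise count.  Accuracy, precision and F1 use a fixed decision
threshold (0.5 by default, canonical for balanced classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .exceptions import CapacityError
from .graph import LabeledPairSet


def auc_score(labels, scores) -> float:
    """Rank-based AUC; ties between classes count 0.5 per pair."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricReport:
    """AUC / accuracy / precision / F1, optionally with per-fold values."""

    auc: float
    accuracy: float
    precision: float
    f1: float
    threshold: float = 0.5
    fold_metrics: list["MetricReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
            "threshold": self.threshold,
        }

    @classmethod
    def mean_of(cls, folds: list["MetricReport"]) -> "MetricReport":
        """Arithmetic mean of per-fold metrics, folds retained."""
        return cls(
            auc=float(np.mean([f.auc for f in folds])),
            accuracy=float(np.mean([f.accuracy for f in folds])),
            precision=float(np.mean([f.precision for f in folds])),
            f1=float(np.mean([f.f1 for f in folds])),
            threshold=folds[0].threshold,
            fold_metrics=list(folds),
        )


def evaluate(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Score a set of predictions against binary labels."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    predicted = (scores >= threshold).astype(int)
    tp = int(((predicted == 1) & (labels == 1)).sum())
    fp = int(((predicted == 1) & (labels == 0)).sum())
    fn = int(((predicted == 0) & (labels == 1)).sum())
    accuracy = float((predicted == labels).mean())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricReport(
        auc=auc_score(labels, scores),
        accuracy=accuracy,
        precision=precision,
        f1=f1,
        threshold=threshold,
    )


@dataclass
class FoldPlan:
    """Stratified fold assignment for every labeled pair."""

    assignments: np.ndarray
    n_folds: int
    seed: int

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if set(np.unique(self.assignments)) != set(range(self.n_folds)):
            raise ValueError("assignments must cover every fold")

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, test indices) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def make_folds(pairs: LabeledPairSet, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified partition of the labeled pairs, deterministic under seed."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = pairs.labels
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise CapacityError(
            f"cannot stratify {counts.min()} pairs of the minority class into {n_folds} folds"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(pairs), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(pairs)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(assignments=assignments, n_folds=n_folds, seed=seed)
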