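"""Binary classification metrics and the 5-fold cross-validation protocol.

Implements accuracy, Matthews correlation coefficient, precision, recall and
false-positive rate from the confusion matrix, ROC AUC by trapezoidal
integration over the ROC curve (equivalently the Mann-Whitney pairwise
statistic with midpoint tie handling), and seeded stratified k-fold CV that
reports mean +/- standard deviation per metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion",
    "acc",
    "precision",
    "recall",
    "fpr",
    "mcc",
    "roc_auc",
    "CVReport",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(pred_labels: Sequence[int], true_labels: Sequence[int]) -> ConfusionCounts:
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(((pred == 1) & (true == 1)).sum()),
        TN=int(((pred == 0) & (true == 0)).sum()),
        FP=int(((pred == 1) & (true == 0)).sum()),
        FN=int(((pred == 0) & (true == 1)).sum()),
    )


def acc(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return (c.TP + c.TN) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 with a warning when no positive predictions."""
    if c.TP + c.FP == 0:
        logger.warning("precision undefined (TP+FP=0); returning 0")
        return 0.0
    return c.TP / (c.TP + c.FP)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN), the true positive rate."""
    if c.TP + c.FN == 0:
        logger.warning("recall undefined (TP+FN=0); returning 0")
        return 0.0
    return c.TP / (c.TP + c.FN)


def fpr(c: ConfusionCounts) -> float:
    """FP / (TN + FP), the false positive rate."""
    if c.TN + c.FP == 0:
        logger.warning("FPR undefined (TN+FP=0); returning 0")
        return 0.0
    return c.FP / (c.TN + c.FP)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 when any marginal is empty (standard convention)."""
    denom2 = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom2 == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom2)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney statistic P(s+ > s-) + 0.5 P(s+ = s-).

    With midpoint tie handling this equals trapezoidal integration of the ROC
    curve exactly; computed via rank sums in O(n log n).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    r = 1
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (r + r + (j - i))  # midrank
        r += j - i + 1
        i = j + 1
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of the empirical ROC curve, thresholds descending."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s) - 1]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp / max(1, (y == 1).sum())]
    fpr_ = np.r_[0.0, fp / max(1, (y == 0).sum())]
    return fpr_, tpr


def trapezoid_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via trapezoidal integration of the ROC curve (cross-check route)."""
    f, t = roc_curve_points(scores, labels)
    return float(np.trapezoid(t, f))


@dataclass
class CVReport:
    """Per-fold confusion counts and scores, plus mean +/- sd summaries."""

    folds: list[dict] = field(default_factory=list)

    METRICS = ("ACC", "AUC", "MCC", "Precision", "Recall")

    def add_fold(self, counts: ConfusionCounts, auc_value: float) -> None:
        self.folds.append(
            {
                "counts": counts,
                "ACC": acc(counts),
                "AUC": auc_value,
                "MCC": mcc(counts),
                "Precision": precision(counts),
                "Recall": recall(counts),
            }
        )

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([f[metric] for f in self.folds], dtype=float)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> str:
        """Table rows like '71.65%±2.06%' (MCC unscaled), one metric per line."""
        rows = []
        for m in self.METRICS:
            mu, sd = self.mean_sd(m)
            if m == "MCC":
                rows.append(f"{m}\t{mu:.4f}±{sd:.4f}")
            else:
                rows.append(f"{m}\t{100 * mu:.2f}%±{100 * sd:.2f}%")
        return "\n".join(rows)


def cross_validate(
    sequences: Sequence,
    labels: Sequence[int],
    model_factory: Callable,
    folds: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV; trains a fresh model per fold.

    ``model_factory()`` must return an object with ``fit(seqs, labels)`` and
    ``predict_proba(seqs) -> array of positive-class scores``.
    """
    y = np.asarray(labels)
    seqs = list(sequences)
    for cls_label in (0, 1):
        if (y == cls_label).sum() < folds:
            raise ValueError(f"need >= {folds} samples of class {cls_label}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    report = CVReport()
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = model_factory()
        model.fit([seqs[i] for i in train_idx], y[train_idx])
        scores = np.asarray(model.predict_proba([seqs[i] for i in test_idx]))
        preds = (scores >= 0.5).astype(int)
        counts = confusion(preds, y[test_idx])
        report.add_fold(counts, roc_auc(scores, y[test_idx]))
    return report
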