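"""Evaluation: macro metrics, ROC AUC, majority baselines and annotator
agreement on 4x4 risk confusion matrices.

Macro averages are unweighted means over the two classes, so they are
insensitive to the (deliberately imbalanced) test distributions.  Degenerate
0/0 precision or recall is defined as 0.  The annotator-agreement statistic
collapses a 4x4 expert-vs-crowdsource risk matrix through a binary task rule
and reports the positive-class F1 (2TP / (2TP + FP + FN)); F1 is symmetric
under swapping FP and FN, so the choice of which annotator is "reference"
does not change the value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .corpus import BinaryTaskSpec

RISK_ORDER = ("none", "low", "moderate", "severe")


@dataclass
class MetricsReport:
    """Per-task macro metrics, all in [0, 1]."""

    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    macro_auc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "macro_auc": self.macro_auc,
        }


def macro_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[float, float, float, float]:
    """(macro precision, macro recall, macro F1, accuracy) over both classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty input")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average="macro", zero_division=0
    )
    return float(p), float(r), float(f1), float(accuracy_score(y_true, y_pred))


def macro_auc(y_true: Sequence[int], prob_positive: Sequence[float]) -> float:
    """Macro ROC AUC for a binary task.

    Computed as the AUC of the positive-class score (rank / Mann-Whitney
    formulation, ties credited one half); for two classes the AUC of the
    complementary class with complementary scores is identical, so the macro
    average equals this single value.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y_true, np.asarray(prob_positive, dtype=np.float64)))


def evaluate_task(
    y_true: Sequence[int], y_pred: Sequence[int], prob_positive: Sequence[float]
) -> MetricsReport:
    p, r, f1, acc = macro_metrics(y_true, y_pred)
    return MetricsReport(
        macro_precision=p,
        macro_recall=r,
        macro_f1=f1,
        accuracy=acc,
        macro_auc=macro_auc(y_true, prob_positive),
    )


@dataclass
class RiskConfusionMatrix:
    """4x4 counts: rows = expert labels, columns = crowdsource labels,
    both ordered (none, low, moderate, severe)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def agreement_f1(cm: RiskConfusionMatrix, task: BinaryTaskSpec) -> float:
    """Positive-class F1 between expert and crowdsource annotations.

    Both axes are binarized through ``task.positive_set``; the expert axis is
    treated as reference and the crowdsource axis as prediction.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zero")
    pos = np.array([lvl in task.positive_set for lvl in RISK_ORDER])
    tp = int(cm.counts[np.ix_(pos, pos)].sum())
    fn = int(cm.counts[np.ix_(pos, ~pos)].sum())
    fp = int(cm.counts[np.ix_(~pos, pos)].sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def majority_baseline_accuracy(labels: Sequence[int]) -> float:
    """Accuracy of always predicting the most frequent class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty input")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / labels.size)
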