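"""Diagnostic-test evaluation: confusion-matrix metrics and ROC/AUC.

A diagnostic read (here: does the reconstructed CT image show a lesion?) is
scored against ground truth with the classic 2x2 counts — A true positives,
B true negatives, C false positives, D false negatives — and summarized as

    accuracy    = (A + B) / (A + B + C + D)
    specificity =  B / (C + B)
    sensitivity =  A / (D + A)

computed in exact rational arithmetic.  Threshold-free ability is summarized
by the ROC curve (prediction rule: score >= threshold, ties predicted
positive) and its trapezoidal AUC, which equals the tie-aware Mann-Whitney
concordance probability over positive-negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, UndefinedMetricError

__all__ = ["ConfusionMatrix", "DiagnosticMetrics", "confusion_metrics", "RocCurve", "roc_curve"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts A (TP), B (TN), C (FP), D (FN)."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self):
        for name in ("A", "B", "C", "D"):
            val = getattr(self, name)
            if not isinstance(val, (int, np.integer)) or val < 0:
                raise InvalidParameterError(f"count {name} must be a nonnegative integer, got {val!r}")

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy, specificity and sensitivity as fractions in [0, 1]."""

    accuracy: float | Fraction
    specificity: float | Fraction
    sensitivity: float | Fraction

    def as_percentages(self) -> tuple[float, float, float]:
        """The three metrics scaled to percent, in reporting order."""
        return (float(self.accuracy) * 100.0,
                float(self.specificity) * 100.0,
                float(self.sensitivity) * 100.0)


def confusion_metrics(cm: ConfusionMatrix, exact: bool = False) -> DiagnosticMetrics:
    """Accuracy, specificity and sensitivity from a confusion matrix.

    Computed with :class:`fractions.Fraction`; pass ``exact=True`` to get
    the rationals themselves instead of floats.  An empty denominator raises
    :class:`UndefinedMetricError` naming the offending metric.
    """
    if cm.total == 0:
        raise UndefinedMetricError("accuracy", "all four counts are zero")
    if cm.B + cm.C == 0:
        raise UndefinedMetricError("specificity", "no actual negatives (B + C = 0)")
    if cm.A + cm.D == 0:
        raise UndefinedMetricError("sensitivity", "no actual positives (A + D = 0)")
    acc = Fraction(cm.A + cm.B, cm.total)
    spe = Fraction(cm.B, cm.C + cm.B)
    sen = Fraction(cm.A, cm.D + cm.A)
    if exact:
        return DiagnosticMetrics(acc, spe, sen)
    return DiagnosticMetrics(float(acc), float(spe), float(sen))


@dataclass
class RocCurve:
    """ROC curve: descending thresholds with matching FPR/TPR, plus AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC for binary labels and real scores.

    Thresholds are the unique scores in descending order preceded by a
    sentinel above the maximum; at threshold t a case is predicted positive
    iff ``score >= t``.  The curve runs from (0, 0) to (1, 1); AUC is the
    trapezoidal integral of TPR over FPR and equals the tie-aware
    Mann-Whitney concordance probability.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.int64)
    if scores.shape != labels.shape:
        raise InvalidInputError(
            f"scores and labels must have equal length, got {len(scores)} vs {len(labels)}")
    if not np.isin(labels, (0, 1)).all():
        raise InvalidInputError("labels must be binary (0/1)")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("labels must contain at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # index of the last occurrence of each distinct score
    distinct_last = np.flatnonzero(np.diff(s_sorted) != 0)
    distinct_last = np.concatenate([distinct_last, [len(s_sorted) - 1]])
    tp = np.cumsum(l_sorted)[distinct_last]
    fp = np.cumsum(1 - l_sorted)[distinct_last]

    thresholds = np.concatenate([[s_sorted[0] + 1.0], s_sorted[distinct_last]])
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
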