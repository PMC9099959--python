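"""Imbalanced-classification metrics.

Confusion-matrix metrics (recall, precision, F1, specificity, balanced
accuracy, MCC, accuracy) follow the standard formulas with the 0/0 -> 0
convention so that degenerate rows (e.g. a classifier that never predicts
the minority class) report 0 rather than NaN.  AUCROC is the rank
statistic P(score_pos > score_neg) + P(tie)/2; AUPRC is step-wise average
precision with tied scores grouped at a single threshold (no linear
interpolation), the conservative choice for rare positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "classification_metrics",
    "auc_roc",
    "auc_pr",
    "reconstruct_confusion",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    recall: float
    precision: float
    f1: float
    specificity: float
    balanced_accuracy: float
    mcc: float
    accuracy: float
    auc_roc: Optional[float] = None
    auc_pr: Optional[float] = None


def _ratio(num: float, den: float) -> float:
    return 0.0 if den == 0 else num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All threshold-level metrics from a 2x2 confusion matrix."""
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    f1 = _ratio(2 * precision * recall, precision + recall)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    ba = (recall + specificity) / 2.0
    mcc_den = np.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = _ratio(float(cm.tp) * cm.tn - float(cm.fp) * cm.fn, mcc_den)
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    return MetricsReport(
        recall=recall,
        precision=precision,
        f1=f1,
        specificity=specificity,
        balanced_accuracy=ba,
        mcc=mcc,
        accuracy=accuracy,
    )


def auc_roc(y_true, scores) -> float:
    """Rank AUCROC: P(score_pos > score_neg) with half credit for ties."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUCROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties -> half credit
    r_pos = ranks[y == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_pr(y_true, scores) -> float:
    """Average precision: sum of (delta recall) x precision over thresholds.

    Thresholds descend through the distinct score values; tied scores
    enter together.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last entry of each tied-score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[block_end], fp[block_end]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def reconstruct_confusion(
    test_neg: int, test_pos: int, recall: float, specificity: float
) -> ConfusionMatrix:
    """Integer confusion matrix implied by class counts and printed rates.

    Bridges a published per-assay test partition (inactive/active counts)
    and its reported recall/specificity back to TP/FN/TN/FP by nearest-
    integer rounding, so every confusion-derived metric can be recomputed
    and cross-checked against the published values.
    """
    if test_neg <= 0 or test_pos <= 0:
        raise ValueError("test partition counts must be positive")
    if not (0 <= recall <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    tp = round(recall * test_pos)
    tn = round(specificity * test_neg)
    fn = test_pos - tp
    fp = test_neg - tn
    if min(tp, tn, fn, fp) < 0:
        raise ValueError("reconstruction produced a negative cell")
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """Full report from hard predictions plus optional ranking scores."""
    y = np.asarray(y_true)
    p = np.asarray(y_pred)
    cm = ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )
    report = classification_metrics(cm)
    if scores is not None:
        report.auc_roc = auc_roc(y, scores)
        report.auc_pr = auc_pr(y, scores)
    return report
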