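"""Binary-classification metrics: confusion counts, F1, sensitivity/specificity, ROC."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalMetrics", "UndefinedMetricError", "compute_metrics", "roc_auc"]


class UndefinedMetricError(ValueError):
    """Truth contains only one class; rates are undefined."""


@dataclass(frozen=True)
class EvalMetrics:
    """Threshold metrics plus the full ROC sweep.

    ``tpr`` is sensitivity (recall on the positive class), ``tnr`` specificity,
    ``f1`` the harmonic mean of precision and recall on the positive class.
    ``roc`` is a list of (FPR, TPR) points from (0,0) to (1,1), non-decreasing
    in both coordinates.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    f1: float
    tpr: float
    tnr: float
    roc: list[tuple[float, float]]
    auc: float

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)


def _roc_sweep(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """ROC by threshold sweep over the unique scores (descending)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:  # ties move diagonally in one step
            tp += int(y[j])
            fp += int(1 - y[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def roc_auc(roc: list[tuple[float, float]]) -> float:
    """Trapezoidal area under the ROC sweep."""
    pts = np.asarray(roc)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def compute_metrics(scores, labels, threshold: float = 0.5) -> EvalMetrics:
    """Evaluate positive-class scores against binary labels.

    ``scores`` are P(positive); a sample is predicted positive when its score
    is >= ``threshold``. Labels are 1 for positive, 0 for negative, and both
    classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if labels.min() == labels.max():
        raise UndefinedMetricError("need both classes in the truth labels")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * tpr / (precision + tpr) if precision + tpr else 0.0
    roc = _roc_sweep(scores, labels)
    return EvalMetrics(tp=tp, fn=fn, tn=tn, fp=fp, f1=f1, tpr=tpr, tnr=tnr,
                       roc=roc, auc=roc_auc(roc))
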