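"""Evaluation metrics: RMSE, Pearson's R, accuracy/precision/recall/MCC.

Regression tasks are scored with the root mean square error and
Pearson's correlation coefficient; classification with accuracy,
precision, recall and the Matthews correlation coefficient computed
from confusion counts.  Metrics whose defining denominator is zero are
reported as ``None`` (undefined) rather than silently zeroed, since a
zero would corrupt comparisons on degenerate folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import UndefinedStatisticError

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "rmse",
    "pearson_r",
    "classification_metrics",
    "confusion_from_labels",
    "multiclass_metrics",
]


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean square error ``sqrt(mean((y − ŷ)²))``."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 1:
        raise ValueError("y and yhat must be equal-length 1-D vectors, N ≥ 1")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pearson_r(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be equal-length 1-D vectors, N ≥ 2")
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = math.sqrt(float(yc @ yc) * float(pc @ pc))
    if denom == 0.0:
        raise UndefinedStatisticError("constant vector: correlation undefined")
    return float(np.clip((yc @ pc) / denom, -1.0, 1.0))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("need at least one observation")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision, recall, MCC; ``None`` marks an undefined
    metric (zero denominator)."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    mcc: float | None


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Compute the four classification metrics from confusion counts.

    accuracy  = (TP + TN) / (P + N)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    MCC       = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    """
    accuracy = (c.TP + c.TN) / c.total
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom) if denom > 0 else None
    return ClassificationMetrics(accuracy, precision, recall, mcc)


def confusion_from_labels(
    y_true: Sequence, y_pred: Sequence, positive_label=1
) -> ConfusionCounts:
    """Tally binary confusion counts from label/prediction pairs."""
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def multiclass_metrics(
    y_true: Sequence, y_pred: Sequence
) -> dict[str, ClassificationMetrics | float | None]:
    """One-vs-rest metrics per class plus macro averages.

    Returns a mapping class → :class:`ClassificationMetrics`, with extra
    keys ``macro_precision`` / ``macro_recall`` / ``macro_mcc``
    (averaged over classes where the metric is defined) and ``accuracy``
    (plain multiclass accuracy).
    """
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    classes = sorted(set(y_true) | set(y_pred), key=str)
    out: dict = {}
    per_class = {}
    for cls in classes:
        per_class[cls] = classification_metrics(
            confusion_from_labels(y_true, y_pred, positive_label=cls)
        )
    out.update(per_class)
    for name in ("precision", "recall", "mcc"):
        vals = [
            getattr(m, name) for m in per_class.values() if getattr(m, name) is not None
        ]
        out[f"macro_{name}"] = float(np.mean(vals)) if vals else None
    out["accuracy"] = float(
        np.mean([t == p for t, p in zip(y_true, y_pred)])
    )
    return out
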