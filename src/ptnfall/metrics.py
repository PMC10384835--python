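"""Confusion-matrix evaluation metrics for the two-class fall task.

Falls are the positive class.  Accuracy, sensitivity (recall on falls),
specificity (recall on ADLs), precision and F1 are reported as percentages;
a metric whose denominator is zero is reported as NaN with a warning rather
than silently as 0 or 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN tallies; falls are positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix tallies must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        """[[TP, FN], [FP, TN]] - rows actual (fall, no-fall)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale metrics; NaN marks an undefined ratio."""

    acc: float
    sen: float
    spe: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sen": self.sen, "spe": self.spe,
                "precision": self.precision, "f1": self.f1}

    def __str__(self) -> str:
        cells = ", ".join(f"{k}={v:.2f}%" for k, v in self.as_dict().items())
        return f"MetricsReport({cells})"


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 in percent.

    Acc = (TP+TN)/(TP+TN+FP+FN), Sen = TP/(TP+FN), Spe = TN/(TN+FP),
    Precision = TP/(TP+FP), F1 = 2 * Precision * Sen / (Precision + Sen).
    """
    if cm.total == 0:
        raise ValueError("cannot compute metrics of an empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    sen = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spe = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    if np.isnan(sen) or np.isnan(precision) or (precision + sen) == 0:
        if not (np.isnan(sen) or np.isnan(precision)):
            warnings.warn("F1 is undefined (precision + sensitivity is zero); "
                          "reporting NaN", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sen / (precision + sen)
    return MetricsReport(acc=acc, sen=sen, spe=spe, precision=precision, f1=f1)
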