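"""Confusion-matrix bookkeeping and the five evaluation metrics.

The positive class is the healthy-control class: TP counts healthy
images predicted healthy, TN counts disease (T2D) images predicted T2D,
FP counts T2D images called healthy and FN healthy images called T2D.

    BAC = (TP/(TP+FN) + TN/(TN+FP)) / 2
    ACC = (TP+TN) / (TP+TN+FP+FN)
    PRE = TP / (TP+FP)
    REC = TP / (TP+FN)
    F1  = 2·PRE·REC / (PRE+REC)

A metric whose denominator vanishes is reported as NaN and listed in
``MetricsReport.undefined`` — never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix", "compute_metrics"]

POSITIVE_CLASS = "healthy"
NEGATIVE_CLASS = "T2D"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive: str = POSITIVE_CLASS,
) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with the healthy class as positive by default."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricsReport:
    bac: float
    acc: float
    pre: float
    rec: float
    f1: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {"BAC": self.bac, "ACC": self.acc, "PRE": self.pre, "REC": self.rec, "F1": self.f1}


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn, "REC")
    spec = ratio(cm.tn, cm.tn + cm.fp, "BAC")
    bac = (sens + spec) / 2.0
    if math.isnan(bac):
        undefined.add("BAC")
    acc = ratio(cm.tp + cm.tn, cm.total, "ACC")
    pre = ratio(cm.tp, cm.tp + cm.fp, "PRE")
    rec = sens
    if math.isnan(pre) or math.isnan(rec) or (pre + rec) == 0:
        undefined.add("F1")
        f1 = math.nan
    else:
        f1 = 2.0 * pre * rec / (pre + rec)
    return MetricsReport(bac=bac, acc=acc, pre=pre, rec=rec, f1=f1, undefined=frozenset(undefined))
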