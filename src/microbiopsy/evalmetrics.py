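"""Binary classification performance measures from confusion counts.

Accuracy is reported on the percent scale, i.e. (TP+TN)/N x 100 (the
fraction is also carried to avoid unit bugs); sensitivity, specificity,
precision, recall, F-measure, balanced classification rate
BCR = sqrt(sensitivity x specificity) and the Matthews correlation
coefficient are on their natural [0, 1] / [-1, 1] scales.  Any metric
with a zero denominator is reported as NaN and flagged, never silently
replaced by 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class ClfScore:
    accuracy_pct: float
    accuracy_fraction: float
    sensitivity: float
    specificity: float
    bcr: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    counts: ConfusionCounts | None = None
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        d = {
            "accuracy_pct": self.accuracy_pct,
            "accuracy_fraction": self.accuracy_fraction,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "bcr": self.bcr,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "undefined": list(self.undefined),
        }
        if self.counts is not None:
            d["counts"] = {"tp": self.counts.tp, "tn": self.counts.tn,
                           "fp": self.counts.fp, "fn": self.counts.fn}
        return d


def confusion(pred: Sequence, true: Sequence, positive=1) -> ConfusionCounts:
    """2x2 confusion counts with the stated positive class."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    labels = set(np.unique(pred)) | set(np.unique(true))
    if len(labels) > 2:
        raise ValueError(f"expected binary labels, got {sorted(labels)!r}")
    p_pos = pred == positive
    t_pos = true == positive
    return ConfusionCounts(
        tp=int(np.count_nonzero(p_pos & t_pos)),
        tn=int(np.count_nonzero(~p_pos & ~t_pos)),
        fp=int(np.count_nonzero(p_pos & ~t_pos)),
        fn=int(np.count_nonzero(~p_pos & t_pos)),
    )


def clf_metrics(c: ConfusionCounts) -> ClfScore:
    """All performance measures derived from one confusion matrix."""
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = (c.tp + c.tn) / c.n
    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    if math.isnan(sens) or math.isnan(spec):
        undefined.append("bcr")
        bcr = float("nan")
    else:
        bcr = math.sqrt(sens * spec)
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    rec = ratio(c.tp, c.tp + c.fn, "recall")
    if math.isnan(prec) or math.isnan(rec) or prec + rec == 0:
        undefined.append("f_measure")
        f = float("nan")
    else:
        f = 2.0 * prec * rec / (prec + rec)
    denom = ((c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp))
    if denom == 0:
        undefined.append("mcc")
        mcc = float("nan")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return ClfScore(
        accuracy_pct=acc * 100.0,
        accuracy_fraction=acc,
        sensitivity=sens,
        specificity=spec,
        bcr=bcr,
        precision=prec,
        recall=rec,
        f_measure=f,
        mcc=mcc,
        counts=c,
        undefined=tuple(undefined),
    )
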