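"""Confusion counts and the six evaluation metrics.

The positive class is *long-lived*: TP counts proteins correctly
predicted long-lived and TN proteins correctly predicted short-lived.
Metrics are ACC, SEN, SPE, PPV, NPV and the Matthews correlation
coefficient; MCC is the model-selection criterion because it stays
informative under the heavy class imbalance of the training data.
Any metric whose denominator is zero is reported as 0 with a degeneracy
flag rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io import LONG_LIVED, SHORT_LIVED

METRIC_NAMES = ("ACC", "SEN", "SPE", "PPV", "NPV", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    mcc: float
    degenerate: frozenset[str] = frozenset()

    def as_dict(self, ndigits: int | None = None) -> dict[str, float]:
        vals = dict(
            zip(METRIC_NAMES, (self.acc, self.sen, self.spe, self.ppv, self.npv, self.mcc))
        )
        if ndigits is not None:
            vals = {k: round(v, ndigits) for k, v in vals.items()}
        return vals


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionCounts:
    """Count TP/TN/FP/FN with long-lived as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label list length mismatch")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in (SHORT_LIVED, LONG_LIVED) or p not in (SHORT_LIVED, LONG_LIVED):
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if t == LONG_LIVED:
            if p == LONG_LIVED:
                tp += 1
            else:
                fn += 1
        else:
            if p == SHORT_LIVED:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float, flag: str, degenerate: set[str]) -> float:
    if den == 0:
        degenerate.add(flag)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """ACC, SEN, SPE, PPV, NPV, MCC from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any
    factor of the denominator is zero the value is 0 (flagged).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    deg: set[str] = set()
    acc = (tp + tn) / counts.total
    sen = _ratio(tp, tp + fn, "SEN", deg)
    spe = _ratio(tn, tn + fp, "SPE", deg)
    ppv = _ratio(tp, tp + fp, "PPV", deg)
    npv = _ratio(tn, tn + fn, "NPV", deg)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        deg.add("MCC")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom2)
    return MetricReport(acc, sen, spe, ppv, npv, mcc, frozenset(deg))
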