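"""Confusion counts and macro-averaged classification metrics.

Accuracy is (TP+TN)/(TP+TN+FP+FN).  Precision, recall and F1 are computed
twice — once with each class taken as positive — and the reported macro
values are the unweighted means of the two per-class values.  The macro
convention is adopted because it is the one that reproduces published
per-fold tables from their own printed confusion counts (e.g. counts
18/5/0/16 give macro precision (18/23 + 16/16)/2 = 89.13%); a
single-positive-class reading does not.

All metric fields are percentages.  Zero-denominator ratios are reported as
0 with ``undefined=True`` rather than NaN so that fold averaging stays
defined.  Values are kept at full precision; :func:`round2` applies the
half-up 2-decimal rounding used for display.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics",
           "fold_average", "round2"]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the convention of printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts under an explicit positive-class convention."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = "positive"
    negative_class: str = "negative"

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """The same predictions with the positive-class convention flipped."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
                               positive_class=self.negative_class,
                               negative_class=self.positive_class)


@dataclass
class MetricReport:
    """Percent-scale metrics for one evaluation.

    ``*_pos``/``*_neg`` are the per-class values with the stated
    positive/negative class treated as positive in turn; macro values are
    their unweighted means.
    """

    accuracy: float
    precision_pos: float
    recall_pos: float
    f1_pos: float
    precision_neg: float
    recall_neg: float
    f1_neg: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int = 0
    undefined: bool = False

    _METRIC_FIELDS = ("accuracy", "precision_pos", "recall_pos", "f1_pos",
                      "precision_neg", "recall_neg", "f1_neg",
                      "macro_precision", "macro_recall", "macro_f1")

    def rounded(self) -> "MetricReport":
        return replace(self, **{f: round2(getattr(self, f))
                                for f in self._METRIC_FIELDS})

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Exact integer confusion counts for binary labels."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(y_true) | set(y_pred)
    if positive_class not in labels:
        labels = labels | {positive_class}
    if len(labels) > 2:
        raise ValueError(f"expected binary labels, got {sorted(map(str, labels))}")
    negatives = labels - {positive_class}
    negative_class = negatives.pop() if negatives else "not_" + str(positive_class)
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                           positive_class=str(positive_class),
                           negative_class=str(negative_class))


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float, bool]:
    undefined = False
    if tp + fp == 0:
        precision, undefined = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, undefined = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, undefined = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return 100 * precision, 100 * recall, 100 * f1, undefined


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy plus per-class and macro precision/recall/F1 (percent)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated items")
    acc = 100.0 * (c.tp + c.tn) / c.total
    p_pos, r_pos, f_pos, u1 = _prf(c.tp, c.fp, c.fn)
    s = c.swapped()
    p_neg, r_neg, f_neg, u2 = _prf(s.tp, s.fp, s.fn)
    return MetricReport(
        accuracy=acc,
        precision_pos=p_pos, recall_pos=r_pos, f1_pos=f_pos,
        precision_neg=p_neg, recall_neg=r_neg, f1_neg=f_neg,
        macro_precision=(p_pos + p_neg) / 2,
        macro_recall=(r_pos + r_neg) / 2,
        macro_f1=(f_pos + f_neg) / 2,
        n=c.total, undefined=u1 or u2)


def fold_average(reports: list[MetricReport]) -> MetricReport:
    """Unweighted arithmetic mean of per-fold metric reports."""
    if not reports:
        raise ValueError("fold_average needs at least one report")
    means = {f: float(np.mean([getattr(r, f) for r in reports]))
             for f in MetricReport._METRIC_FIELDS}
    return MetricReport(**means, n=sum(r.n for r in reports),
                        undefined=any(r.undefined for r in reports))
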