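"""Confusion counts and classification metrics with per-class + macro reporting.

The reporting convention mirrors clinical-ML result tables: each metric is
computed twice, once per class treated as positive, and an "Average" row is
the unweighted mean of the two per-class rows.  The per-class "accuracy"
column holds that class's recall (the per-class tally), while the overall
accuracy (TP+TN)/total is reported separately and unambiguously.

All internal math is full precision; percentages are rounded half-up to two
decimals only at the reporting boundary.  Degenerate 0/0 ratios come back as
0 with a flag rather than raising, so metaheuristic fitness loops never
abort mid-search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Rate",
    "confusion_counts",
    "precision",
    "recall",
    "accuracy",
    "f_measure",
    "mcc",
    "kappa",
    "ClassMetrics",
    "class_metrics",
    "MetricsRow",
    "ClassMetricsReport",
    "macro_report",
    "round_percent",
]

COLUMN_ORDER = ("accuracy", "precision", "recall", "f_measure", "mcc", "kappa")
COLUMN_HEADERS = ("Accu_y", "Prec_n", "Reca_l", "F_Measure", "MCC", "Kappa")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally with respect to a stated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive class exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


class Rate(float):
    """A rate in [0, 1] carrying a degenerate-denominator flag."""

    degenerate: bool

    def __new__(cls, value: float, degenerate: bool = False) -> "Rate":
        obj = super().__new__(cls, value)
        obj.degenerate = degenerate
        return obj


def _ratio(num: float, den: float) -> Rate:
    if den == 0:
        return Rate(0.0, degenerate=True)
    return Rate(num / den)


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    """Standard 2x2 tally of predictions against truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    alphabet = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(alphabet) > 2:
        raise ValueError(f"expected a two-label alphabet, got {sorted(map(str, alphabet))}")
    if positive not in alphabet:
        raise ValueError(f"positive label {positive!r} absent from labels {sorted(map(str, alphabet))}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def precision(c: ConfusionCounts) -> Rate:
    """P = TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> Rate:
    return _ratio(c.tp, c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> Rate:
    """Overall accuracy (TP + TN) / total."""
    return _ratio(c.tp + c.tn, c.total)


def f_measure(c: ConfusionCounts) -> Rate:
    p, r = precision(c), recall(c)
    if p + r == 0:
        return Rate(0.0, degenerate=True)
    return Rate(2 * p * r / (p + r), degenerate=p.degenerate or r.degenerate)


def mcc(c: ConfusionCounts) -> Rate:
    """Matthews correlation from the 2x2 table."""
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        return Rate(0.0, degenerate=True)
    return Rate((c.tp * c.tn - c.fp * c.fn) / sqrt(den))


def kappa(c: ConfusionCounts) -> Rate:
    """Cohen's kappa with chance agreement from the marginals."""
    n = c.total
    if n == 0:
        return Rate(0.0, degenerate=True)
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    if p_e == 1:
        return Rate(0.0, degenerate=True)
    return Rate((p_o - p_e) / (1 - p_e))


@dataclass(frozen=True)
class ClassMetrics:
    """All metrics for one table; accuracy here is the overall (TP+TN)/total."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    kappa: float
    degenerate: frozenset = frozenset()


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    if c.total == 0:
        raise ValueError("empty confusion table")
    values = {
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "f_measure": f_measure(c),
        "mcc": mcc(c),
        "kappa": kappa(c),
    }
    flagged = frozenset(k for k, v in values.items() if v.degenerate)
    return ClassMetrics(**{k: float(v) for k, v in values.items()}, degenerate=flagged)


@dataclass(frozen=True)
class MetricsRow:
    """One report row in table column order; accuracy = per-class recall."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    kappa: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, k) for k in COLUMN_ORDER)


def _mean_row(rows: list[MetricsRow]) -> MetricsRow:
    return MetricsRow(*(float(np.mean([r.as_tuple()[i] for r in rows])) for i in range(6)))


@dataclass
class ClassMetricsReport:
    """Per-class rows, their unweighted average, and the overall accuracy."""

    per_class: dict
    average: MetricsRow
    overall_accuracy: float
    degenerate: bool = False

    def to_json(self) -> str:
        def row_doc(r: MetricsRow):
            return {h: round_percent(v) for h, v in zip(COLUMN_HEADERS, r.as_tuple())}

        doc = {
            "per_class": {str(k): row_doc(r) for k, r in self.per_class.items()},
            "average": row_doc(self.average),
            "overall_accuracy": round_percent(self.overall_accuracy),
            "degenerate": self.degenerate,
        }
        return json.dumps(doc, indent=2)

    def to_text(self) -> str:
        """Aligned table in standard column order (values in percent)."""
        width = max(len(str(k)) for k in self.per_class) + 2
        width = max(width, len("Average") + 2)
        lines = ["".join(["Classes".ljust(width)] + [h.rjust(11) for h in COLUMN_HEADERS])]
        for k, r in list(self.per_class.items()) + [("Average", self.average)]:
            cells = [f"{round_percent(v):.2f}".rjust(11) for v in r.as_tuple()]
            lines.append("".join([str(k).ljust(width)] + cells))
        lines.append(f"Overall accuracy: {round_percent(self.overall_accuracy):.2f}")
        return "\n".join(lines)


def round_percent(rate: float) -> float:
    """Rate in [0,1] -> percent rounded half-up to two decimals.

    The value is first written at six decimals so that a true decimal half
    (e.g. 92.975) is not lost to binary representation before the half-up
    rounding.
    """
    return float(Decimal(f"{rate * 100:.6f}").quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def macro_report(y_true, y_pred, class_order=None) -> ClassMetricsReport:
    """Compute each metric with each class as positive and average them.

    ``class_order`` fixes the row order (defaults to descending label, so a
    0/1 presence label puts presence first).  A single-class truth vector
    yields a report flagged degenerate rather than an exception.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if class_order is None:
        class_order = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)), reverse=True)
    degenerate = len(np.unique(y_true)) < 2
    rows = {}
    overall = None
    for label in class_order:
        c = confusion_counts(y_true, y_pred, positive=label)
        m = class_metrics(c)
        # per-class accuracy column = that class's recall (per-class tally)
        rows[label] = MetricsRow(
            accuracy=m.recall, precision=m.precision, recall=m.recall,
            f_measure=m.f_measure, mcc=m.mcc, kappa=m.kappa,
        )
        overall = m.accuracy  # identical whichever class is positive
    return ClassMetricsReport(
        per_class=rows,
        average=_mean_row(list(rows.values())),
        overall_accuracy=float(overall),
        degenerate=degenerate,
    )
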