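"""Confusion-matrix statistics with explicit undefined-value semantics.

Binary safety-pharmacology classifiers are routinely summarized by nine
statistics derived from the confusion matrix.  On strongly biased models
whole rows or columns of the matrix can be empty (for example a model that
never predicts the positive class has TP = FP = 0), which makes precision,
the F-measure and the Matthews correlation coefficient division-by-zero
cases.  Published tables mark such cells with a dash; here they carry an
explicit :data:`UNDEFINED` marker rather than a silent NaN or an imputed
zero, and any statistic derived from an undefined one is undefined as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Union

import numpy as np

__all__ = [
    "UNDEFINED",
    "Undefined",
    "ConfusionMatrix",
    "MetricReport",
    "compute_metrics",
    "pct_inactive",
    "confusion_from_calls",
]


class Undefined:
    """Singleton marker for a statistic whose denominator is zero."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # matches the dash used in printed tables
        return "–"

    def __bool__(self) -> bool:
        return False


UNDEFINED = Undefined()

MetricValue = Union[float, Undefined]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts of a binary confusion matrix (positive = active)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def total_positive(self) -> int:
        """Number of truly active samples."""
        return self.tp + self.fn

    @property
    def total_negative(self) -> int:
        """Number of truly inactive samples."""
        return self.tn + self.fp


def confusion_from_calls(y_true, y_pred) -> ConfusionMatrix:
    """Tabulate a :class:`ConfusionMatrix` from parallel 0/1 vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> MetricValue:
    return UNDEFINED if den == 0 else num / den


@dataclass(frozen=True)
class MetricReport:
    """The nine confusion-matrix statistics, each a float or UNDEFINED.

    ``recall`` is definitionally identical to ``sensitivity`` and is kept as
    a separate field because evaluation tables list both.  The ``rounded``
    view applies round-half-even at ``ndigits`` decimals, the convention
    used for reporting; comparisons against printed tables should allow
    ±0.005.
    """

    sensitivity: MetricValue
    specificity: MetricValue
    balanced_accuracy: MetricValue
    accuracy: MetricValue
    precision: MetricValue
    npv: MetricValue
    recall: MetricValue
    f_measure: MetricValue
    mcc: MetricValue
    ndigits: int = field(default=2, compare=False)

    _ORDER = (
        "balanced_accuracy",
        "accuracy",
        "recall",
        "precision",
        "sensitivity",
        "specificity",
        "f_measure",
        "mcc",
        "npv",
    )

    def rounded(self) -> dict[str, MetricValue]:
        """Report view rounded at ``ndigits`` (round-half-even)."""
        out: dict[str, MetricValue] = {}
        for name in self._ORDER:
            v = getattr(self, name)
            out[name] = v if v is UNDEFINED else round(v, self.ndigits)
        return out

    def as_dict(self, rounded: bool = False) -> dict[str, MetricValue]:
        if rounded:
            return self.rounded()
        return {name: getattr(self, name) for name in self._ORDER}

    def as_row(self, rounded: bool = True) -> dict[str, object]:
        """Row with dash markers, in the column order of evaluation tables."""
        src = self.as_dict(rounded=rounded)
        return {k: ("–" if v is UNDEFINED else v) for k, v in src.items()}


def compute_metrics(cm: ConfusionMatrix, ndigits: int = 2) -> MetricReport:
    """Compute the nine statistics from a confusion matrix.

    Formulas::

        sensitivity = TP / (TP + FN)
        specificity = TN / (TN + FP)
        balanced accuracy = (sensitivity + specificity) / 2
        accuracy = (TP + TN) / (TP + FP + TN + FN)
        precision (PPV) = TP / (TP + FP)
        NPV = TN / (TN + FN)
        recall = TP / (TP + FN)
        F = 2 * precision * recall / (precision + recall)
        MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

    Any zero denominator yields :data:`UNDEFINED`, and statistics that
    depend on an undefined one (F on precision, MCC on any empty margin)
    are undefined as well.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ba = UNDEFINED if sens is UNDEFINED or spec is UNDEFINED else (sens + spec) / 2
    acc = _ratio(tp + tn, cm.total)
    prec = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    recall = sens
    if prec is UNDEFINED or recall is UNDEFINED or (prec + recall) == 0:
        f = UNDEFINED
    else:
        f = 2 * prec * recall / (prec + recall)
    denom_factors = ((tp + fn), (tp + fp), (tn + fp), (tn + fn))
    if any(d == 0 for d in denom_factors):
        mcc: MetricValue = UNDEFINED
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(float(d) for d in denom_factors))
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        accuracy=acc,
        precision=prec,
        npv=npv,
        recall=recall,
        f_measure=f,
        mcc=mcc,
        ndigits=ndigits,
    )


def pct_inactive(n_inactive: int, n_active: int, ndigits: int = 2) -> float:
    """Percentage of inactives, ``100*n_inactive/(n_inactive+n_active)``.

    Reported rounded (round-half-even) at ``ndigits``; pass ``ndigits=None``
    for the unrounded value (used internally by selection filters so that
    threshold tests are free of rounding artifacts).
    """
    total = n_inactive + n_active
    if total < 1:
        raise ValueError("at least one compound required")
    if n_inactive < 0 or n_active < 0:
        raise ValueError("counts must be non-negative")
    pct = 100.0 * n_inactive / total
    return pct if ndigits is None else round(pct, ndigits)


def roc_auc(y_true, scores) -> float:
    """ROC AUC from continuous scores (convenience; needs both classes)."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))
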