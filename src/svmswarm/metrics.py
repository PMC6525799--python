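"""Confusion matrix, nine derived scores, and exact integer inversion.

The nine measures of a binary confusion matrix (``+1`` = positive class):

====================  =======================================================
accuracy              (TP + TN) / (TP + TN + FP + FN)
precision             TP / (TP + FP)
recall                TP / (TP + FN)
f1                    harmonic mean of precision and recall
fpr (fall-out)        FP / (FP + TN)
fdr                   FP / (FP + TP)
fnr (miss rate)       FN / (FN + TP)
npv                   TN / (TN + FN)
mcc                   (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
====================  =======================================================

Rational metrics are computed in exact ``fractions.Fraction`` arithmetic and
rounded to float only on output; a zero denominator yields ``None``
(explicitly undefined), never a silent zero.

:func:`reconstruct_confusion_matrix` inverts a row of *printed, rounded*
metric values back to the integer confusion matrices consistent with them at
a known total ``n``, by exhaustive enumeration — useful for auditing
published results tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np

from .data import InvalidLabel, LengthMismatch, NoSolution, SvmSwarmError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "compute_metrics_exact",
    "reconstruct_confusion_matrix",
    "printed_tolerance",
    "METRIC_ORDER",
]

#: Canonical column order for reports (results-table convention).
METRIC_ORDER = (
    "accuracy",
    "precision",
    "recall",
    "f1",
    "fpr",
    "fdr",
    "fnr",
    "npv",
    "mcc",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classifier: true/false positives/negatives."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise SvmSwarmError(f"{name} must be a nonnegative integer")
        if self.total < 1:
            raise SvmSwarmError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with ``+1`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise LengthMismatch("y_true and y_pred differ in length")
    for arr in (y_true, y_pred):
        if not np.all(np.isin(arr, (-1, 1))):
            raise InvalidLabel("labels must be +1 or -1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
    )


def _ratio(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def compute_metrics_exact(cm: ConfusionMatrix) -> dict[str, Fraction | float | None]:
    """All nine metrics; rational ones as exact Fractions, MCC as float.

    ``None`` marks an undefined value (zero denominator).
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    mcc_den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den2 == 0 else (tp * tn - fp * fn) / math.sqrt(mcc_den2)
    return {
        "accuracy": _ratio(tp + tn, cm.total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "fpr": _ratio(fp, fp + tn),
        "fdr": _ratio(fp, fp + tp),
        "fnr": _ratio(fn, fn + tp),
        "npv": _ratio(tn, tn + fn),
        "mcc": mcc,
    }


@dataclass(frozen=True)
class MetricsReport:
    """The nine scores as floats; ``None`` = undefined for this matrix."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    fpr: float | None
    fdr: float | None
    fnr: float | None
    npv: float | None
    mcc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_ORDER}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_csv_line(self, percent: bool = True) -> str:
        """One CSV line in :data:`METRIC_ORDER`. With ``percent=True`` the
        first four columns are scaled to percentages (results-table style)."""
        cells = []
        for i, name in enumerate(METRIC_ORDER):
            v = getattr(self, name)
            if v is None:
                cells.append("undefined")
            else:
                cells.append(f"{100 * v:.4f}" if percent and i < 4 else f"{v:.4f}")
        return ",".join(cells)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Nine-score report of a confusion matrix (floats, ``None`` if undefined)."""
    exact = compute_metrics_exact(cm)
    return MetricsReport(
        **{k: (None if v is None else float(v)) for k, v in exact.items()}
    )


def printed_tolerance(decimals: int) -> float:
    """Half-ULP tolerance of a value printed with ``decimals`` decimal places."""
    return 0.5 * 10.0 ** (-decimals)


def reconstruct_confusion_matrix(
    printed: Mapping[str, float],
    n: int,
    tol: Mapping[str, float] | float = 5e-5,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices with total ``n`` matching printed metrics.

    Parameters
    ----------
    printed : mapping of metric name to printed value
        Values on their natural scale (rates in [0, 1], mcc in [-1, 1]); at
        least two metrics are required for a meaningful inversion.
    n : int
        Total number of classified cases.
    tol : float or mapping
        Absolute matching tolerance per metric — typically the half-ULP of
        the printed precision (:func:`printed_tolerance`). A scalar applies
        to every metric.

    Returns
    -------
    list of ConfusionMatrix
        Every consistent matrix (the caller asserts uniqueness). A candidate
        for which a supplied metric is undefined never matches.

    Raises
    ------
    NoSolution
        If no matrix is consistent with the printed values.
    """
    if n < 1:
        raise SvmSwarmError("n must be >= 1")
    unknown = set(printed) - set(METRIC_ORDER)
    if unknown:
        raise SvmSwarmError(f"unknown metric name(s): {sorted(unknown)}")
    if len(printed) < 2:
        raise SvmSwarmError("need at least two printed metrics to invert")
    if not isinstance(tol, Mapping):
        tol = {name: float(tol) for name in printed}
    solutions: list[ConfusionMatrix] = []
    for tp in range(n + 1):
        for fp in range(n + 1 - tp):
            for fn in range(n + 1 - tp - fp):
                cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn)
                exact = compute_metrics_exact(cm)
                ok = True
                for name, target in printed.items():
                    v = exact[name]
                    if v is None or abs(float(v) - target) > tol.get(name, 5e-5):
                        ok = False
                        break
                if ok:
                    solutions.append(cm)
    if not solutions:
        raise NoSolution(f"no confusion matrix with n={n} matches the printed metrics")
    return solutions
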