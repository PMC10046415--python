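"""Classification metrics: confusion matrices, per-class DSC/MCC, fold averaging.

The two figures of merit are the Dice similarity coefficient,

    DSC = 2 TP / (2 TP + FP + FN),

and the Matthews correlation coefficient,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

both computed one-vs-rest per class from the confusion matrix of each
fold's validation split, then averaged arithmetically across folds.  MCC
uses the true-negative count as well and tends to report lower (more
conservative) values than DSC, but this is an empirical tendency, not a
theorem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassCounts",
    "MetricReport",
    "confusion_matrix",
    "one_vs_rest_counts",
    "dice",
    "mcc",
    "report_from_predictions",
    "fold_average",
]


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest contingency counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(predictions, truths, n_classes: int) -> np.ndarray:
    """Counts matrix with entry (i, j) = #(truth i predicted j)."""
    y_pred = np.asarray(predictions, dtype=np.int64)
    y_true = np.asarray(truths, dtype=np.int64)
    if y_pred.shape != y_true.shape:
        raise ValueError("predictions and truths must have equal length")
    if y_pred.size and (
        y_pred.min() < 0 or y_true.min() < 0 or y_pred.max() >= n_classes or y_true.max() >= n_classes
    ):
        raise ValueError(f"labels out of range for {n_classes} classes")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def one_vs_rest_counts(cm: np.ndarray, c: int) -> ClassCounts:
    """Collapse a multi-class confusion matrix to binary counts for class c."""
    tp = int(cm[c, c])
    fn = int(cm[c].sum() - tp)
    fp = int(cm[:, c].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(counts: ClassCounts) -> float:
    """Dice similarity coefficient; NaN (with warning) when the class is empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn("DSC undefined: no positives in truth or prediction", stacklevel=2)
        return float("nan")
    return 2.0 * counts.tp / denom


def mcc(counts: ClassCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when degenerate."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    dm = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if dm == 0:
        warnings.warn("MCC degenerate (a marginal is zero); returning 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(dm))


@dataclass(frozen=True)
class MetricReport:
    """Per-class metrics plus the aggregated confusion matrix.

    ``dsc``/``mcc`` hold one value per class (fold-averaged when built via
    :func:`fold_average`).  ``confusion`` is summed over folds, so its total
    equals the number of evaluated validation samples.
    """

    class_names: tuple[str, ...]
    dsc: np.ndarray
    mcc: np.ndarray
    confusion: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    @property
    def n_misclassified(self) -> int:
        return int(self.confusion.sum() - np.trace(self.confusion))

    @property
    def misclassification_rate(self) -> float:
        return self.n_misclassified / self.n_samples

    @property
    def accuracy(self) -> float:
        return 1.0 - self.misclassification_rate

    def to_rows(self) -> list[dict]:
        return [
            {"class": name, "DSC": float(self.dsc[i]), "MCC": float(self.mcc[i])}
            for i, name in enumerate(self.class_names)
        ]


def report_from_predictions(predictions, truths, class_names: tuple[str, ...]) -> MetricReport:
    """Single-split report: one-vs-rest DSC and MCC for every class."""
    n_classes = len(class_names)
    cm = confusion_matrix(predictions, truths, n_classes)
    counts = [one_vs_rest_counts(cm, c) for c in range(n_classes)]
    return MetricReport(
        class_names=tuple(class_names),
        dsc=np.array([dice(c) for c in counts]),
        mcc=np.array([mcc(c) for c in counts]),
        confusion=cm,
    )


def fold_average(per_fold: list[MetricReport]) -> MetricReport:
    """Arithmetic mean of per-class metrics over folds; confusion matrices summed."""
    if not per_fold:
        raise ValueError("need at least one fold report")
    names = per_fold[0].class_names
    if any(r.class_names != names for r in per_fold):
        raise ValueError("fold reports cover different class sets")
    return MetricReport(
        class_names=names,
        dsc=np.nanmean(np.stack([r.dsc for r in per_fold]), axis=0),
        mcc=np.nanmean(np.stack([r.mcc for r in per_fold]), axis=0),
        confusion=np.sum(np.stack([r.confusion for r in per_fold]), axis=0),
    )
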