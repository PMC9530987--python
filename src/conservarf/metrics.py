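"""Confusion matrices and every evaluation statistic the screening workflow
reports: balanced accuracy, per-class recall, sensitivity/specificity/precision,
the multi-class Matthews correlation coefficient, macro-averaged F-score, and
applicability-domain coverage.

Balanced accuracy is the mean of the per-class recalls,

    BA = (1/n) * sum_i TP_i / (TP_i + FN_i),

which makes it robust to the severe Inactive/Active imbalance typical of
receptor-activity datasets: an always-Inactive predictor scores 1/n, not the
Inactive prevalence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import ActivityLabels


@dataclass
class ConfusionMatrix:
    """k x k counts, rows = observed class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_names = tuple(self.class_names)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k matching class_names")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(observed: ActivityLabels,
              predicted: Sequence[int]) -> ConfusionMatrix:
    pred = np.asarray(predicted, dtype=int)
    y = observed.labels
    if pred.shape != y.shape:
        raise ValueError("observed and predicted lengths differ")
    k = observed.n_classes
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y, pred), 1)
    return ConfusionMatrix(counts, observed.class_names)


def per_class_recall(cm: ConfusionMatrix, *,
                     ignore_empty: bool = False) -> np.ndarray:
    """Recall of each observed class (TP_i over row sum i).

    With ``ignore_empty`` classes that never occur get NaN instead of raising;
    by default an empty observed class is an error naming the class.
    """
    row_sums = cm.counts.sum(axis=1)
    if not ignore_empty and (row_sums == 0).any():
        empty = cm.class_names[int(np.flatnonzero(row_sums == 0)[0])]
        raise ValueError(f"observed class {empty!r} has no substances")
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.diag(cm.counts) / row_sums
    return rec


def balanced_accuracy(cm: ConfusionMatrix, *,
                      ignore_empty: bool = False) -> float:
    """Mean of per-class recalls.

    ``ignore_empty=True`` averages over the classes actually observed, which
    is needed when evaluation is restricted to an applicability domain that
    may exclude every member of a rare class.
    """
    rec = per_class_recall(cm, ignore_empty=ignore_empty)
    if ignore_empty:
        rec = rec[~np.isnan(rec)]
        if rec.size == 0:
            raise ValueError("no observed class has any substances")
    return float(np.mean(rec))


def binary_stats(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, precision and recall of a 2x2 matrix.

    The Active (stronger, index 1) class is the positive class.  An undefined
    precision (no predicted positives) is reported as NaN, never as 0.
    """
    if cm.n_classes != 2:
        raise ValueError("binary_stats requires a 2x2 confusion matrix")
    tn, fp = cm.counts[0]
    fn, tp = cm.counts[1]
    sensitivity = tp / (tp + fn) if tp + fn else math.nan
    specificity = tn / (tn + fp) if tn + fp else math.nan
    precision = tp / (tp + fp) if tp + fp else math.nan
    return {
        "sensitivity": float(sensitivity),
        "specificity": float(specificity),
        "precision": float(precision),
        "recall": float(sensitivity),
    }


def mcc(cm: ConfusionMatrix) -> float:
    """Multi-class Matthews correlation coefficient (the R_k statistic).

    Reduces to the classical (TP*TN - FP*FN)/sqrt(...) formula for two
    classes.  A degenerate matrix (single observed and predicted class, zero
    denominator) is defined as 0 with a warning.
    """
    c = cm.counts.astype(float)
    t = c.sum(axis=1)  # observed per class
    p = c.sum(axis=0)  # predicted per class
    s = c.sum()
    correct = np.trace(c)
    num = correct * s - float(t @ p)
    den = math.sqrt(s * s - float(p @ p)) * math.sqrt(s * s - float(t @ t))
    if den == 0.0:
        warnings.warn("degenerate confusion matrix; MCC defined as 0",
                      stacklevel=2)
        return 0.0
    return float(num / den)


def macro_f(cm: ConfusionMatrix, beta: float = 1.0) -> float:
    """Unweighted mean of per-class one-vs-rest F_beta scores.

    A class whose F score is undefined (no observed members and no
    predictions, or zero precision and recall) contributes 0 — required for
    split scoring on small nodes where a class is absent.
    """
    c = cm.counts.astype(float)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    b2 = beta * beta
    scores = np.zeros(cm.n_classes)
    for i in range(cm.n_classes):
        denom = (1 + b2) * tp[i] + b2 * fn[i] + fp[i]
        scores[i] = (1 + b2) * tp[i] / denom if denom > 0 else 0.0
    return float(scores.mean())


def coverage(in_domain_flags: Sequence[bool]) -> float:
    """Fraction of substances inside the applicability domain."""
    flags = np.asarray(in_domain_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("coverage of an empty set is undefined")
    return float(flags.mean())


def metrics_report(cm: ConfusionMatrix) -> dict[str, float]:
    """The standard metric block for one confusion matrix."""
    rep: dict[str, float] = {
        "balanced_accuracy": balanced_accuracy(cm, ignore_empty=True),
        "mcc": mcc(cm),
        "macro_f1": macro_f(cm),
        "n": cm.total,
    }
    if cm.n_classes == 2:
        rep.update(binary_stats(cm))
    return rep
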