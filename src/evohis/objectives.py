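"""Confusion-count bookkeeping and objective arithmetic.

The three primary objectives are prediction accuracy (PAC), specificity
(SPY, true-negative rate) and sensitivity (SEY, true-positive rate); they
are scalarized into a single fitness ``Z = w1*PAC + w2*SPY + w3*SEY``
under weights that sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedObjectiveError, WeightConstraintError

__all__ = [
    "ConfusionCounts",
    "ObjectiveVector",
    "ObjectiveWeights",
    "confusion_counts",
    "primary_objectives",
    "scalarize",
    "secondary_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled TP/TN/FP/FN counts; ``tp + fn`` positives, ``tn + fp`` negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class ObjectiveVector:
    """(PAC, SEY, SPY) triple, each in [0, 1]."""

    pac: float
    sey: float
    spy: float

    def __post_init__(self):
        for name in ("pac", "sey", "spy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pac, self.sey, self.spy], dtype=float)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Scalarization weights (w1 for PAC, w2 for SPY, w3 for SEY)."""

    w1: float = 0.95
    w2: float = 0.025
    w3: float = 0.025

    def __post_init__(self):
        for name in ("w1", "w2", "w3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise WeightConstraintError(f"{name}={v} outside [0, 1]")
        total = self.w1 + self.w2 + self.w3
        if abs(total - 1.0) > 1e-9:
            raise WeightConstraintError(f"weights must sum to 1, got {total}")


def confusion_counts(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary label vectors (1 = positive, 0 = negative)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length: {t.shape} vs {p.shape}")
    for arr, which in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr).tolist()) - {0, 1}
        if bad:
            raise ValueError(f"{which} labels outside {{0, 1}}: {sorted(bad)}")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    m1 = int(np.sum(t == 1))
    m2 = int(np.sum(t == 0))
    return ConfusionCounts(tp=tp, tn=tn, fp=m2 - tn, fn=m1 - tp)


def primary_objectives(cc: ConfusionCounts) -> ObjectiveVector:
    """PAC = (TP+TN)/N, SPY = TN/(TN+FP), SEY = TP/(TP+FN)."""
    if cc.n_positive == 0 or cc.n_negative == 0:
        raise UndefinedObjectiveError(
            f"objectives undefined: m1={cc.n_positive}, m2={cc.n_negative}"
        )
    return ObjectiveVector(
        pac=(cc.tp + cc.tn) / cc.total,
        sey=cc.tp / cc.n_positive,
        spy=cc.tn / cc.n_negative,
    )


def scalarize(obj: ObjectiveVector, weights: ObjectiveWeights) -> float:
    """Weighted-sum fitness Z = w1*PAC + w2*SPY + w3*SEY."""
    return weights.w1 * obj.pac + weights.w2 * obj.spy + weights.w3 * obj.sey


def secondary_metrics(cc: ConfusionCounts) -> dict:
    """Class-weighted precision, recall and F-measure (Weka summary convention).

    Per-class values are weighted by class support; an undefined per-class
    metric (zero denominator) contributes 0 with a warning.  The weighted
    recall equals PAC by construction.
    """
    n = cc.total
    w_pos, w_neg = cc.n_positive / n, cc.n_negative / n

    def _ratio(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator); contributing 0")
            return 0.0
        return num / den

    prec_pos = _ratio(cc.tp, cc.tp + cc.fp, "positive-class precision")
    prec_neg = _ratio(cc.tn, cc.tn + cc.fn, "negative-class precision")
    rec_pos = _ratio(cc.tp, cc.tp + cc.fn, "positive-class recall")
    rec_neg = _ratio(cc.tn, cc.tn + cc.fp, "negative-class recall")
    f_pos = _ratio(2 * prec_pos * rec_pos, prec_pos + rec_pos, "positive-class F1")
    f_neg = _ratio(2 * prec_neg * rec_neg, prec_neg + rec_neg, "negative-class F1")
    return {
        "precision": w_pos * prec_pos + w_neg * prec_neg,
        "recall": w_pos * rec_pos + w_neg * rec_neg,
        "f_measure": w_pos * f_pos + w_neg * f_neg,
    }
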