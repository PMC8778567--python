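"""Confusion-matrix metrics for the two-class screening report.

Accuracy is reported as a percentage; precision, recall, specificity and
F-score as fractions.  Two F-score variants are provided: the ``standard``
harmonic-mean form 2TP/(2TP+FP+FN), and an ``as_printed`` variant
2TP/(2TP+FP+TN) preserved for fidelity with a widely circulated misprint of
the formula (TN in place of FN).  A metric whose denominator is zero is
reported as NaN (undefined), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "metric_suite", "METRIC_NAMES"]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f_score")

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tallies: true/false positives and negatives."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    y_true: Sequence,
    y_pred: Sequence,
    positive_class,
) -> ConfusionCounts:
    """Tally the 2x2 confusion counts with the stated positive class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    pos_t = t == positive_class
    pos_p = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def metric_suite(c: ConfusionCounts, f_variant: str = "standard") -> dict[str, float]:
    """Accuracy (%), precision, recall, specificity and F-score.

    ``f_variant`` selects the F-score denominator: ``"standard"`` uses
    2TP + FP + FN; ``"as_printed"`` uses 2TP + FP + TN.
    """
    if f_variant not in ("standard", "as_printed"):
        raise ValueError(f"unknown f_variant {f_variant!r}")
    if c.total == 0:
        raise ValueError("empty confusion table")
    acc = _ratio(c.tp + c.tn, c.total)
    accuracy = acc * 100.0 if not math.isnan(acc) else UNDEFINED
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    if f_variant == "standard":
        f_score = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    else:
        f_score = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.tn)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f_score": f_score,
    }
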