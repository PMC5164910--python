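"""Pixelwise confusion-matrix evaluation of binary vessel masks.

Metrics follow the standard definitions on pixel counts, reported as
percentages:

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)

A metric whose denominator is zero (an empty positive or negative class)
is reported as NaN — the "undefined" marker — and excluded from aggregate
means with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricSet", "confusion_counts", "metrics", "aggregate", "dice"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity / specificity / accuracy in percent (NaN = undefined)."""

    sensitivity: float
    specificity: float
    accuracy: float


def _as_binary(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    values = np.unique(arr)
    if np.isin(values, (0, 1)).all() or np.isin(values, (0, 255)).all():
        return arr > 0
    raise ValueError(
        f"{name} mask is not binary: values must be boolean, 0/1 or 0/255, "
        f"found {values[:10]}"
    )


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Exact TP/TN/FP/FN pixel counts of a predicted mask against truth."""
    p = _as_binary(pred, "predicted")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Percent sensitivity, specificity and accuracy from pixel counts."""
    return MetricSet(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
    )


def aggregate(per_image: list[MetricSet]) -> MetricSet:
    """Unweighted arithmetic mean of each metric over a set of images.

    Undefined (NaN) entries are excluded from the corresponding mean; the
    number excluded is logged.  An all-undefined metric aggregates to NaN.
    """
    if not per_image:
        raise ValueError("cannot aggregate an empty list of metric sets")
    means = {}
    for name in ("sensitivity", "specificity", "accuracy"):
        vals = np.array([getattr(ms, name) for ms in per_image], dtype=float)
        n_undef = int(np.isnan(vals).sum())
        if n_undef:
            logger.warning("%d undefined %s value(s) excluded from the mean", n_undef, name)
        means[name] = float(np.nanmean(vals)) if n_undef < vals.size else math.nan
    return MetricSet(**means)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = _as_binary(a, "first")
    b = _as_binary(b, "second")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(np.count_nonzero(a)) + int(np.count_nonzero(b))
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom
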