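"""Detection performance metrics per ROI and aggregated per case.

Ratios with zero denominators (e.g. positive-stratum recall in an ROI with no
positive reference cells) are undefined and reported as NaN; median
aggregation skips them and pooled aggregation absorbs them by summing raw
counts first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .matching import MatchResult


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN if either is NaN or both zero."""
    if math.isnan(precision) or math.isnan(recall):
        return math.nan
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class DetectionMetrics:
    """TP/FP/FN counts with the derived rate metrics.

    ``fdr = fp/(tp+fp) = 1 - precision``; ``precision = tp/(tp+fp)``;
    ``recall = tp/(tp+fn)``; ``f_score`` the harmonic mean of the two.
    Undefined ratios are NaN.
    """

    tp: int
    fp: int
    fn: int
    fdr: float
    precision: float
    recall: float
    f_score: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "DetectionMetrics":
        precision = tp / (tp + fp) if tp + fp > 0 else math.nan
        recall = tp / (tp + fn) if tp + fn > 0 else math.nan
        return cls(
            tp=tp,
            fp=fp,
            fn=fn,
            fdr=1.0 - precision if not math.isnan(precision) else math.nan,
            precision=precision,
            recall=recall,
            f_score=f_score(precision, recall),
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "fdr": self.fdr, "precision": self.precision,
            "recall": self.recall, "f_score": self.f_score,
        }


def metrics_from_match(m: MatchResult) -> DetectionMetrics:
    """Detection metrics of one capped assignment: TP = matched pairs,
    FN = unmatched reference dots, FP = unmatched detections."""
    return DetectionMetrics.from_counts(tp=m.n_tp, fp=m.n_fp, fn=m.n_fn)


def _as_metrics(item: Union[MatchResult, DetectionMetrics]) -> DetectionMetrics:
    if isinstance(item, MatchResult):
        return metrics_from_match(item)
    return item


def aggregate_case(
    items: Sequence[Union[MatchResult, DetectionMetrics]],
    mode: str = "pooled",
) -> DetectionMetrics:
    """Aggregate per-ROI results over one case (or any group of ROIs).

    ``pooled`` sums TP/FP/FN across ROIs and derives the ratios from the
    sums; ``median`` takes the median of the per-ROI ratios, skipping
    undefined (NaN) entries.  In median mode the count fields still carry the
    summed counts, but the ratio fields are medians and need not satisfy the
    count identities.
    """
    if not items:
        raise ValidationError("aggregate_case requires a non-empty list")
    ms = [_as_metrics(it) for it in items]
    tp = sum(m.tp for m in ms)
    fp = sum(m.fp for m in ms)
    fn = sum(m.fn for m in ms)
    if mode == "pooled":
        return DetectionMetrics.from_counts(tp, fp, fn)
    if mode == "median":
        def med(vals: Iterable[float]) -> float:
            arr = np.array([v for v in vals if not math.isnan(v)])
            return float(np.median(arr)) if arr.size else math.nan

        return DetectionMetrics(
            tp=tp, fp=fp, fn=fn,
            fdr=med(m.fdr for m in ms),
            precision=med(m.precision for m in ms),
            recall=med(m.recall for m in ms),
            f_score=med(m.f_score for m in ms),
        )
    raise ValidationError(f"unknown aggregation mode {mode!r}")


@dataclass(frozen=True)
class CountComparison:
    """Per-unit tallies of detector counts vs reference counts."""

    n_over: int
    n_under: int
    n_equal: int

    @property
    def n_units(self) -> int:
        return self.n_over + self.n_under + self.n_equal

    def to_dict(self) -> dict:
        return {
            "n_over": self.n_over, "n_under": self.n_under,
            "n_equal": self.n_equal, "n_units": self.n_units,
        }


def compare_counts(ref_counts: Sequence[float], det_counts: Sequence[float]) -> CountComparison:
    """Tally in how many units (ROIs/cases) the detector strictly over-counts,
    under-counts, or matches the reference."""
    ref = np.asarray(ref_counts, dtype=float)
    det = np.asarray(det_counts, dtype=float)
    if ref.shape != det.shape or ref.ndim != 1:
        raise ValidationError("ref_counts and det_counts must be equal-length 1-D series")
    return CountComparison(
        n_over=int(np.sum(det > ref)),
        n_under=int(np.sum(det < ref)),
        n_equal=int(np.sum(det == ref)),
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares regression line ``y = slope·x + intercept``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("linear_fit requires two equal-length series with n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant; regression slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)
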