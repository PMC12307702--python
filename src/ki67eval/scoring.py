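"""Ki67 proliferation-index computation and WHO grading of NETs.

The Ki67 score of an ROI is the percentage of tumor cells whose nuclei stain
positive.  The case-level score sums positive and total counts over all ROIs
of the slide before dividing — not the mean of per-ROI percentages, which
would weight sparse ROIs the same as dense ones.

WHO grade bands for gastrointestinal neuroendocrine tumors (by Ki67 score):
G1 < 3%, G2 3-20% inclusive, G3 > 20%.  Grading is applied to the unrounded
score: the 3% boundary is clinically decisive, separating low-grade from
intermediate-grade tumors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .annotations import AnnotationSet
from .errors import ValidationError


class Grade(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


@dataclass(frozen=True)
class Ki67Score:
    """Positive and total tumor-cell counts with the derived percentage.

    ``score_pct`` is ``100 * n_positive / n_total`` or NaN when the set is
    empty (undefined score).
    """

    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_positive > self.n_total or self.n_positive < 0:
            raise ValidationError(
                f"invalid counts: {self.n_positive} positive of {self.n_total}"
            )

    @property
    def score_pct(self) -> float:
        if self.n_total == 0:
            return math.nan
        return 100.0 * self.n_positive / self.n_total

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    def to_dict(self) -> dict:
        return {
            "n_positive": self.n_positive,
            "n_total": self.n_total,
            "score_pct": self.score_pct,
        }


def roi_score(aset: AnnotationSet) -> Ki67Score:
    """Ki67 score of one ROI: positive dots divided by all dots."""
    if not aset.labeled:
        raise ValidationError(
            f"set {aset.source}/{aset.roi_id} is unlabeled; cannot score"
        )
    return Ki67Score(n_positive=aset.n_positive, n_total=aset.n_total)


def case_score(rois: Sequence[Ki67Score]) -> Ki67Score:
    """Case-level score: counts summed across the slide's ROIs, then divided."""
    if not rois:
        raise ValidationError("case_score requires at least one ROI score")
    return Ki67Score(
        n_positive=sum(r.n_positive for r in rois),
        n_total=sum(r.n_total for r in rois),
    )


def grade(score: Ki67Score) -> Grade:
    """WHO grade from a Ki67 score: G1 < 3%, G2 3-20% (inclusive), G3 > 20%."""
    if not score.defined:
        raise ValidationError("cannot grade an undefined (0-cell) score")
    pct = score.score_pct
    if pct < 3.0:
        return Grade.G1
    if pct <= 20.0:
        return Grade.G2
    return Grade.G3


def grade_changed(reference: Ki67Score, detector: Ki67Score) -> bool:
    """Whether the detector's score falls in a different WHO grade band than
    the reference standard's — the clinically relevant failure mode."""
    return grade(reference) != grade(detector)
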