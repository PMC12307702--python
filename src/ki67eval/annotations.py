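"""Domain types and file I/O for dot annotations of tumor-cell nuclei.

A region of interest (ROI) from a Ki67-stained slide is annotated with one dot
per tumor cell, each labeled positive (Ki67-stained) or negative.  Dots live in
a pixel coordinate frame with the origin at the ROI's top-left corner, x
rightward and y downward; coordinates are continuous (sub-pixel positions are
allowed), matching what image viewers such as ImageJ export from multi-point
ROIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

POSITIVE = "positive"
NEGATIVE = "negative"
_VALID_LABELS = (POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class CoordinateFrame:
    """Pixel grid of one ROI (or mark-up image) plus its physical resolution.

    Parameters
    ----------
    width_px, height_px : int
        Image size in pixels; at least 1.
    um_per_px : float
        Physical resolution in micrometres per pixel; strictly positive.
    """

    width_px: int
    height_px: int
    um_per_px: float

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValidationError(
                f"frame size must be >= 1 px, got {self.width_px}x{self.height_px}"
            )
        if not self.um_per_px > 0:
            raise ValidationError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def width_um(self) -> float:
        """Physical width of the frame in micrometres."""
        return self.width_px * self.um_per_px

    @property
    def height_um(self) -> float:
        return self.height_px * self.um_per_px

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "um_per_px": self.um_per_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoordinateFrame":
        return cls(int(d["width_px"]), int(d["height_px"]), float(d["um_per_px"]))


@dataclass(frozen=True)
class PointAnnotation:
    """One dot marking: continuous pixel coordinates plus a binary Ki67 label."""

    x: float
    y: float
    label: str = NEGATIVE

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValidationError(
                f"label must be one of {_VALID_LABELS}, got {self.label!r}"
            )


@dataclass
class AnnotationSet:
    """All dots of one ROI from one source (reference standard or a detector).

    ``labeled`` is False when the originating file carried no label column; the
    points are then all stored as negative and label-dependent operations
    refuse the set.
    """

    roi_id: str
    case_id: str
    source: str
    frame: CoordinateFrame
    points: list[PointAnnotation] = field(default_factory=list)
    labeled: bool = True

    def __post_init__(self) -> None:
        self.points = list(self.points)
        for i, p in enumerate(self.points):
            if not (0 <= p.x < self.frame.width_px and 0 <= p.y < self.frame.height_px):
                raise ValidationError(
                    f"point {i} of {self.source}/{self.roi_id} at ({p.x}, {p.y}) "
                    f"falls outside the {self.frame.width_px}x{self.frame.height_px} frame"
                )

    # -- counting -----------------------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self.points)

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.points if p.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return self.n_total - self.n_positive

    # -- array views --------------------------------------------------------
    def xy(self) -> np.ndarray:
        """Coordinates as an (n, 2) float array in pixel units."""
        if not self.points:
            return np.empty((0, 2), dtype=float)
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    def positive_mask(self) -> np.ndarray:
        return np.array([p.label == POSITIVE for p in self.points], dtype=bool)

    def subset(self, indices: Iterable[int], suffix: str = "") -> "AnnotationSet":
        """A new set containing ``points[i]`` for each ``i`` in order."""
        return AnnotationSet(
            roi_id=self.roi_id + suffix,
            case_id=self.case_id,
            source=self.source,
            frame=self.frame,
            points=[self.points[i] for i in indices],
            labeled=self.labeled,
        )

    def with_points(self, points: Sequence[PointAnnotation]) -> "AnnotationSet":
        return AnnotationSet(
            roi_id=self.roi_id,
            case_id=self.case_id,
            source=self.source,
            frame=self.frame,
            points=list(points),
            labeled=self.labeled,
        )

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "case_id": self.case_id,
            "source": self.source,
            "frame": self.frame.to_dict(),
            "labeled": self.labeled,
            "points": [[p.x, p.y, p.label] for p in self.points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSet":
        return cls(
            roi_id=d["roi_id"],
            case_id=d["case_id"],
            source=d["source"],
            frame=CoordinateFrame.from_dict(d["frame"]),
            points=[PointAnnotation(float(x), float(y), lab) for x, y, lab in d["points"]],
            labeled=bool(d.get("labeled", True)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def concat_sets(sets: Sequence[AnnotationSet]) -> AnnotationSet:
    """Concatenate ROI sets of one case/source into a single set.

    All sets must share one coordinate frame and labeling status.  Used for
    case-level scoring, where counts are summed across the eight ROIs.
    """
    if not sets:
        raise ValidationError("cannot concatenate an empty list of sets")
    first = sets[0]
    for s in sets[1:]:
        if s.frame != first.frame:
            raise ValidationError("cannot concatenate sets with differing frames")
    return AnnotationSet(
        roi_id="+".join(s.roi_id for s in sets),
        case_id=first.case_id,
        source=first.source,
        frame=first.frame,
        points=[p for s in sets for p in s.points],
        labeled=all(s.labeled for s in sets),
    )


def _find_column(columns: Sequence[str], name: str) -> str | None:
    for c in columns:
        if str(c).strip().lower() == name:
            return c
    return None


def read_points(
    path: str | Path,
    frame: CoordinateFrame,
    source: str,
    roi_id: str = "",
    case_id: str = "",
) -> AnnotationSet:
    """Read a dot-annotation CSV (ImageJ multi-point "Measure" style).

    The file must have a header with ``X`` and ``Y`` columns (case-insensitive,
    pixel units of ``frame``); an optional ``Label`` column holds
    ``positive``/``negative``.  Without a label column every point is stored as
    negative and the returned set is flagged unlabeled.  Row order is
    preserved.

    Raises
    ------
    FormatError
        If X or Y is missing from the header.
    ValidationError
        If a coordinate falls outside the frame or a label is unrecognized;
        the message names the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    xcol = _find_column(df.columns, "x")
    ycol = _find_column(df.columns, "y")
    if xcol is None or ycol is None:
        raise FormatError(f"{path}: CSV header must contain X and Y columns")
    labcol = _find_column(df.columns, "label")

    xs = df[xcol].to_numpy(dtype=float)
    ys = df[ycol].to_numpy(dtype=float)
    labs = df[labcol].astype(str).to_list() if labcol is not None else None

    points: list[PointAnnotation] = []
    for i in range(len(df)):
        row_number = i + 2  # 1-based, after the header line
        x, y = float(xs[i]), float(ys[i])
        if labs is not None:
            raw = labs[i].strip().lower()
            if raw not in _VALID_LABELS:
                raise ValidationError(
                    f"{path} row {row_number}: unrecognized label {raw!r} "
                    f"(expected one of {_VALID_LABELS})"
                )
            label: str = raw
        else:
            label = NEGATIVE
        if not (0 <= x < frame.width_px and 0 <= y < frame.height_px):
            raise ValidationError(
                f"{path} row {row_number}: point ({x}, {y}) outside "
                f"{frame.width_px}x{frame.height_px} frame"
            )
        points.append(PointAnnotation(x, y, label))

    return AnnotationSet(
        roi_id=roi_id or path.stem,
        case_id=case_id,
        source=source,
        frame=frame,
        points=points,
        labeled=labcol is not None,
    )


def write_points(aset: AnnotationSet, path: str | Path) -> None:
    """Write a set back to CSV with columns X, Y, Label (6-decimal coordinates).

    Round-trips through :func:`read_points` reproduce coordinates to 1e-6 px
    and labels exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("X,Y,Label\n")
        for p in aset.points:
            fh.write(f"{p.x:.6f},{p.y:.6f},{p.label}\n")
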