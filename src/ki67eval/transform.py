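"""Coordinate transformation between frames of differing size and resolution.

Detector mark-up images are resampled renderings of the same physical ROI as
the reference image, so mapping between them is a pure axis-aligned scaling
(no rotation; an optional translation offset is accepted for robustness but
defaults to zero).  All sources are mapped onto one grid before point
matching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationSet, CoordinateFrame, PointAnnotation
from .errors import ExtentMismatchError, FrameMismatchError

#: Relative tolerance on the physical extents of two frames that claim to
#: cover the same region.
DEFAULT_EXTENT_RTOL = 0.01


@dataclass(frozen=True)
class FrameMapping:
    """Affine scale (plus optional offset) taking source-frame px to target-frame px."""

    source: CoordinateFrame
    target: CoordinateFrame
    sx: float
    sy: float
    tx: float = 0.0
    ty: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.sx == 1.0 and self.sy == 1.0 and self.tx == 0.0 and self.ty == 0.0

    def inverse(self) -> "FrameMapping":
        return FrameMapping(
            source=self.target,
            target=self.source,
            sx=1.0 / self.sx,
            sy=1.0 / self.sy,
            tx=-self.tx / self.sx,
            ty=-self.ty / self.sy,
        )

    def to_dict(self) -> dict:
        return {
            "source": self.source.to_dict(),
            "target": self.target.to_dict(),
            "sx": self.sx,
            "sy": self.sy,
            "tx": self.tx,
            "ty": self.ty,
        }


def build_mapping(
    source: CoordinateFrame,
    target: CoordinateFrame,
    *,
    offset_px: tuple[float, float] = (0.0, 0.0),
    extent_rtol: float = DEFAULT_EXTENT_RTOL,
    allow_extent_mismatch: bool = False,
) -> FrameMapping:
    """Build the scaling that maps ``source`` pixels onto the ``target`` grid.

    Scale factors are ratios of pixel sizes, ``sx = target.width_px /
    source.width_px`` (same for y).  Both frames must describe the same
    physical region: their extents in µm must agree within ``extent_rtol``
    unless ``allow_extent_mismatch`` is set.

    Raises
    ------
    ExtentMismatchError
        If the physical extents disagree beyond tolerance.
    """
    if not allow_extent_mismatch:
        for axis, s_ext, t_ext in (
            ("x", source.width_um, target.width_um),
            ("y", source.height_um, target.height_um),
        ):
            if not math.isclose(s_ext, t_ext, rel_tol=extent_rtol):
                raise ExtentMismatchError(
                    f"{axis}-extent mismatch: source {s_ext:.3f} µm vs "
                    f"target {t_ext:.3f} µm exceeds rtol={extent_rtol}"
                )
    sx = target.width_px / source.width_px
    sy = target.height_px / source.height_px
    if not math.isclose(sx, sy, rel_tol=1e-6):
        warnings.warn(
            f"anisotropic scaling (sx={sx:.6g}, sy={sy:.6g}); distance-capped "
            "matching assumes isotropic distances",
            stacklevel=2,
        )
    return FrameMapping(source=source, target=target, sx=sx, sy=sy,
                        tx=float(offset_px[0]), ty=float(offset_px[1]))


def identity_mapping(frame: CoordinateFrame) -> FrameMapping:
    return FrameMapping(source=frame, target=frame, sx=1.0, sy=1.0)


def apply_mapping(mapping: FrameMapping, aset: AnnotationSet) -> AnnotationSet:
    """Map every point of ``aset`` into the mapping's target frame.

    Labels and point order are preserved; the result's frame is the target.
    Points that land exactly on the far edge through floating-point rounding
    are nudged just inside (the frame uses half-open bounds).
    """
    if aset.frame != mapping.source:
        raise FrameMismatchError(
            f"set frame {aset.frame} does not match mapping source {mapping.source}"
        )
    tgt = mapping.target
    new_points = []
    for p in aset.points:
        x = p.x * mapping.sx + mapping.tx
        y = p.y * mapping.sy + mapping.ty
        if x == tgt.width_px:
            x = np.nextafter(x, 0.0)
        if y == tgt.height_px:
            y = np.nextafter(y, 0.0)
        new_points.append(PointAnnotation(x, y, p.label))
    return AnnotationSet(
        roi_id=aset.roi_id,
        case_id=aset.case_id,
        source=aset.source,
        frame=tgt,
        points=new_points,
        labeled=aset.labeled,
    )
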