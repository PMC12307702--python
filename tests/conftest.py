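import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ki67eval.annotations import (
    NEGATIVE,
    POSITIVE,
    AnnotationSet,
    CoordinateFrame,
    PointAnnotation,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_frame() -> CoordinateFrame:
    """100x100 px frame at 1 µm/px: distances in px equal distances in µm."""
    return CoordinateFrame(width_px=100, height_px=100, um_per_px=1.0)


@pytest.fixture
def roi_frame() -> CoordinateFrame:
    """The 200 µm ROI frame at scanner resolution."""
    return CoordinateFrame(width_px=870, height_px=870, um_per_px=0.23)


def make_set(
    coords,
    labels=None,
    frame=None,
    source="test",
    roi_id="roi",
    case_id="case",
) -> AnnotationSet:
    """Build an AnnotationSet from (x, y) pairs; labels default to negative."""
    frame = frame or CoordinateFrame(width_px=100, height_px=100, um_per_px=1.0)
    if labels is None:
        labels = [NEGATIVE] * len(coords)
    pts = [PointAnnotation(float(x), float(y), lab)
           for (x, y), lab in zip(coords, labels)]
    return AnnotationSet(roi_id=roi_id, case_id=case_id, source=source,
                         frame=frame, points=pts)


def random_instance(rng: np.random.Generator, n_ref: int, n_det: int,
                    frame=None, labeled_frac=0.3):
    """Random reference/detector pair inside one frame, with random labels."""
    frame = frame or CoordinateFrame(width_px=100, height_px=100, um_per_px=1.0)
    def draw(n, source):
        coords = rng.uniform(0, [frame.width_px, frame.height_px], size=(n, 2))
        labels = [POSITIVE if rng.random() < labeled_frac else NEGATIVE
                  for _ in range(n)]
        return make_set(coords, labels, frame=frame, source=source)
    return draw(n_ref, "reference"), draw(n_det, "detector")
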