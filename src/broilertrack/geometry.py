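"""Bounding-box geometry shared by every pipeline stage.

Coordinate convention: origin at the top-left of the frame, x increasing
rightwards, y increasing downwards, continuous pixel units.  Boxes are stored
as (left, top, width, height) — the MOT-Challenge CSV layout — and overlap is
computed on closed intervals, so two boxes sharing only an edge have zero
intersection area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BoundingBox",
    "StateObservation",
    "PixelScale",
    "iou",
    "iou_matrix",
    "box_to_observation",
    "observation_to_box",
    "px_to_meters",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box: the unit of detection, annotation and tracking.

    Parameters
    ----------
    left, top : float
        Pixel coordinates of the top-left corner.
    width, height : float
        Box side lengths in pixels; must be strictly positive.
    """

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"degenerate box: width={self.width}, height={self.height} "
                "(both sides must be > 0)"
            )

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_center(
        cls, cx: float, cy: float, width: float, height: float
    ) -> "BoundingBox":
        return cls(cx - width / 2.0, cy - height / 2.0, width, height)


@dataclass(frozen=True)
class StateObservation:
    """Box re-expressed in the tracker's measurement space.

    ``x, y`` are the box center, ``s`` the area (scale) in px² and ``r`` the
    aspect ratio width/height.
    """

    x: float
    y: float
    s: float
    r: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.r > 0):
            raise ValueError(f"invalid observation: s={self.s}, r={self.r}")


@dataclass(frozen=True)
class PixelScale:
    """Linear pixel→metric conversion for the top-down camera.

    The default is anchored to the one printed equivalence for this pen
    (a mean broiler radius of 59 px = 13.5 cm).
    """

    meters_per_px: float = 0.135 / 59.0

    def __post_init__(self) -> None:
        if not self.meters_per_px > 0:
            raise ValueError("meters_per_px must be > 0")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1].

    Symmetric; 0 for disjoint boxes (sharing an edge counts as disjoint),
    1 iff the boxes are identical.
    """
    ix = min(a.right, b.right) - max(a.left, b.left)
    iy = min(a.bottom, b.bottom) - max(a.top, b.top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return min(inter / (a.area + b.area - inter), 1.0)


def iou_matrix(rows, cols):
    """Pairwise IOU between two box sequences as an (len(rows), len(cols)) array."""
    import numpy as np

    if len(rows) == 0 or len(cols) == 0:
        return np.zeros((len(rows), len(cols)))
    ra = np.array([[b.left, b.top, b.right, b.bottom] for b in rows])
    ca = np.array([[b.left, b.top, b.right, b.bottom] for b in cols])
    ix = np.minimum(ra[:, None, 2], ca[None, :, 2]) - np.maximum(
        ra[:, None, 0], ca[None, :, 0]
    )
    iy = np.minimum(ra[:, None, 3], ca[None, :, 3]) - np.maximum(
        ra[:, None, 1], ca[None, :, 1]
    )
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_r = (ra[:, 2] - ra[:, 0]) * (ra[:, 3] - ra[:, 1])
    area_c = (ca[:, 2] - ca[:, 0]) * (ca[:, 3] - ca[:, 1])
    return np.minimum(inter / (area_r[:, None] + area_c[None, :] - inter), 1.0)


def box_to_observation(b: BoundingBox) -> StateObservation:
    """Convert a box to the (x, y, s, r) measurement convention."""
    cx, cy = b.center
    return StateObservation(cx, cy, b.width * b.height, b.width / b.height)


def observation_to_box(o: StateObservation) -> BoundingBox:
    """Inverse of :func:`box_to_observation`: width = sqrt(s·r), height = s/width."""
    width = math.sqrt(o.s * o.r)
    height = o.s / width
    return BoundingBox.from_center(o.x, o.y, width, height)


def px_to_meters(d: float, scale: PixelScale) -> float:
    """Convert a non-negative pixel distance to meters."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return d * scale.meters_per_px
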