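"""Geometric primitives: axis-aligned boxes, detections, and the IoU overlap metric.

Coordinate convention (used everywhere in this package): continuous pixel
coordinates, origin at the image's top-left corner, x to the right, y
*downward*.  A box spans the half-open region ``[x1, x2) x [y1, y2)``, so two
boxes that merely share an edge do not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "Detection",
    "FrameDetections",
    "iou",
    "box_to_measurement",
    "measurement_to_box",
]


@dataclass(frozen=True)
class Box:
    """An axis-aligned bounding box ``[x1, x2) x [y1, y2)`` in pixel coordinates.

    Degenerate boxes (zero or negative area, non-finite corners) are rejected
    at construction so that downstream geometry never has to special-case them.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v):
                raise ValueError(f"box coordinates must be finite, got {self!r}")
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"box must have strictly positive area: ({self.x1},{self.y1},{self.x2},{self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        """Build from top-left corner plus width/height (MOT convention)."""
        return cls(x, y, x + w, y + h)

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Box":
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass(frozen=True)
class Detection:
    """A detector output: a box, its confidence score, and its frame index."""

    box: Box
    confidence: float
    frame: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.frame < 0:
            raise ValueError(f"frame index must be non-negative, got {self.frame}")


@dataclass
class FrameDetections:
    """All detections belonging to one frame, in input order."""

    frame: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.frame != self.frame:
                raise ValueError(
                    f"detection frame {d.frame} != container frame {self.frame}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes.

    Returns ``|a ∩ b| / (|a| + |b| - |a ∩ b|)``, a symmetric overlap score in
    [0, 1]; 1 for identical boxes, 0 when the half-open boxes are disjoint.
    """
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def box_to_measurement(b: Box) -> np.ndarray:
    """Convert a box to the filter's observation vector ``(cx, cy, a, h)``.

    ``cx, cy`` is the center, ``a`` the width/height aspect ratio, and ``h``
    the height — the standard observation parameterisation for box tracking.
    """
    cx, cy = b.center
    h = b.height
    return np.array([cx, cy, b.width / h, h], dtype=float)


def measurement_to_box(m: Sequence[float] | np.ndarray) -> Box:
    """Exact inverse of :func:`box_to_measurement`."""
    cx, cy, a, h = (float(v) for v in m)
    w = a * h
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def group_by_frame(detections: Iterable[Detection]) -> list[FrameDetections]:
    """Bucket detections into per-frame containers, sorted by frame index."""
    buckets: dict[int, list[Detection]] = {}
    for d in detections:
        buckets.setdefault(d.frame, []).append(d)
    return [FrameDetections(f, buckets[f]) for f in sorted(buckets)]
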