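"""Person detection: the detector contract plus a depth-difference oracle.

The recognition pipeline only needs, per frame, the bounding box of the one
resident in the room.  Production systems plug in a trained object detector
behind the :class:`Detector` protocol; for synthetic scenes with a known
empty background the :func:`oracle_depth_detector` recovers the person as
the connected foreground region that sits nearer to the camera than the
background plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .colorization import ColorFrame, ColorizationRange, DepthFrame, recover_frame


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, half-open pixel interval [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"box extends outside frame: {self}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union with another box."""
        ix = max(0, min(self.x1, other.x1) - max(self.x0, other.x0))
        iy = max(0, min(self.y1, other.y1) - max(self.y0, other.y0))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union else 0.0


@runtime_checkable
class Detector(Protocol):
    """Contract: map a colorized frame to zero or more person boxes."""

    def detect(self, frame: ColorFrame) -> List[BoundingBox]:
        ...


def oracle_depth_detector(
    frame: DepthFrame,
    background: DepthFrame,
    min_delta: float = 0.15,
    min_area: int = 200,
) -> List[BoundingBox]:
    """Foreground boxes from depth differencing against a known background.

    A pixel is foreground when it is at least ``min_delta`` meters nearer to
    the camera than the empty-scene background.  Foreground pixels are
    grouped into 8-connected components; components smaller than ``min_area``
    pixels are discarded.  Returns the tight box of each surviving component
    with confidence 1.0, sorted by decreasing area.
    """
    if frame.values.shape != background.values.shape:
        raise ValueError(
            f"dimension mismatch: frame {frame.values.shape} vs background {background.values.shape}"
        )
    fg = (background.values - frame.values) > min_delta
    labeled, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    boxes: List[BoundingBox] = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        ys, xs = sl
        region = labeled[sl] > 0
        if int(region.sum()) < min_area:
            continue
        boxes.append(
            BoundingBox(x0=xs.start, y0=ys.start, x1=xs.stop, y1=ys.stop, confidence=1.0)
        )
    boxes.sort(key=lambda b: -b.area)
    return boxes


def select_primary_box(boxes: List[BoundingBox]) -> Optional[BoundingBox]:
    """Pick the single box the pipeline tracks (one resident per room).

    Largest area wins; ties fall to higher confidence, then to the smaller
    ``(y0, x0)`` corner.  ``None`` for an empty list (no-person frame).
    """
    if not boxes:
        return None
    return min(boxes, key=lambda b: (-b.area, -b.confidence, b.y0, b.x0))


@dataclass
class DepthOracleDetector:
    """:class:`Detector` adapter running the depth oracle on colorized input.

    Decodes each color frame back to depth with the configured range, then
    applies :func:`oracle_depth_detector` against the stored background.
    Deterministic for a fixed frame and configuration.
    """

    background: DepthFrame
    colorization_range: ColorizationRange
    min_delta: float = 0.15
    min_area: int = 200

    def detect(self, frame: ColorFrame) -> List[BoundingBox]:
        depth = recover_frame(frame, self.colorization_range)
        return oracle_depth_detector(depth, self.background, self.min_delta, self.min_area)
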