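"""Windowed depth appearance/motion features described by HOG.

A five-frame window of normalized person crops is summarized by two
128 x 128 maps — Depth Motion Appearance (DMA), the mean depth shape of the
window, and Depth Motion History (DMH), a recency-coded record of where
depth changed — each described by a Histogram of Oriented Gradients and
concatenated into a single 16,200-dimensional vector.

HOG geometry: 9 unsigned orientation bins over 8 x 8-pixel cells, 2 x 2-cell
blocks at one-cell stride, per-block L2 normalization.  On a 128 x 128 map
that is 15 x 15 blocks x 4 cells x 9 bins = 8100 entries per map, hence
16,200 for the DMA+DMH concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from PIL import Image
from skimage.feature import hog

from .colorization import ColorFrame, ColorizationRange, recover_frame
from .detection import BoundingBox

#: Frames per feature window; features fire once per five frames.
WINDOW_LENGTH = 5
#: Side of the normalized square person crop, in pixels.
CROP_SIZE = 128
#: Minimum inter-frame depth change (m) counted as motion by the DMH map.
DEFAULT_MOTION_EPSILON = 0.05

HOG_ORIENTATIONS = 9
HOG_CELL = (8, 8)
HOG_BLOCK = (2, 2)

#: Descriptor length for one 128 x 128 feature map.
HOG_DIM = 8100
#: Length of the concatenated DMA+DMH descriptor.
DESCRIPTOR_DIM = 2 * HOG_DIM


@dataclass
class FeatureWindow:
    """Exactly five consecutive normalized depth crops, shape (5, H, W)."""

    crops: np.ndarray
    frame_indices: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.crops = np.asarray(self.crops, dtype=np.float64)
        if self.crops.ndim != 3 or self.crops.shape[0] != WINDOW_LENGTH:
            raise ValueError(
                f"window must hold {WINDOW_LENGTH} equally sized crops, got shape {self.crops.shape}"
            )
        if not np.all(np.isfinite(self.crops)):
            raise ValueError("window contains non-finite depths")


@dataclass
class FeatureMap:
    """One 8-bit-scaled map ([0, 255]) of kind ``"DMA"`` or ``"DMH"``."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("DMA", "DMH"):
            raise ValueError(f"kind must be 'DMA' or 'DMH', got {self.kind!r}")
        if self.values.min() < 0 or self.values.max() > 255:
            raise ValueError("feature map values must lie in [0, 255]")


def crop_resize_recover(
    color: ColorFrame,
    box: BoundingBox,
    rng: ColorizationRange,
    size: int = CROP_SIZE,
) -> np.ndarray:
    """Crop the person from a colorized frame, normalize size, decode depth.

    The crop is resized to ``size x size`` in color space (bilinear) and only
    then decoded to metric depth, so downstream stages always see crops of
    one fixed geometry.
    """
    if box.x1 > color.width or box.y1 > color.height:
        raise ValueError(f"box {box} extends outside frame {color.height}x{color.width}")
    patch = color.pixels[box.y0 : box.y1, box.x0 : box.x1]
    img = Image.fromarray(patch, mode="RGB").resize((size, size), Image.BILINEAR)
    resized = ColorFrame(pixels=np.asarray(img, dtype=np.uint8))
    return recover_frame(resized, rng).values


def compute_dma(window: FeatureWindow) -> FeatureMap:
    """Depth Motion Appearance: mean depth over the window, min-max scaled.

    The per-pixel mean of the five crops captures the person's overall shape
    and posture; it is min-max scaled onto [0, 255] and quantized to integer
    gray levels (a constant window maps to all zeros).
    """
    mean = window.crops.mean(axis=0)
    lo, hi = float(mean.min()), float(mean.max())
    if hi == lo:
        return FeatureMap(values=np.zeros_like(mean), kind="DMA")
    scaled = (mean - lo) / (hi - lo) * 255.0
    return FeatureMap(values=np.floor(scaled + 0.5), kind="DMA")


def compute_dmh(window: FeatureWindow, epsilon: float = DEFAULT_MOTION_EPSILON) -> FeatureMap:
    """Depth Motion History: recency-coded map of where depth changed.

    For each consecutive frame pair t-1 -> t (t = 2..5), pixels whose depth
    changed by more than ``epsilon`` meters receive intensity
    ``255 * (t - 1) / 4``; later motion overwrites earlier, so a pixel's
    value tells how recently it moved (most recent pair -> 255).  Pixels
    that never move stay 0.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    out = np.zeros(window.crops.shape[1:], dtype=np.float64)
    for t in range(1, WINDOW_LENGTH):
        moved = np.abs(window.crops[t] - window.crops[t - 1]) > epsilon
        out[moved] = np.floor(255.0 * t / (WINDOW_LENGTH - 1) + 0.5)
    return FeatureMap(values=out, kind="DMH")


def hog_descriptor(feature_map: FeatureMap | np.ndarray) -> np.ndarray:
    """HOG descriptor of one feature map.

    9 unsigned bins, 8 x 8 cells, overlapping 2 x 2 blocks, L2 block norm.
    128 x 128 input -> 8100 entries; other cell-aligned sizes follow the
    block-count formula (e.g. 64 x 64 -> 1764, a diagnostic mode).
    """
    values = feature_map.values if isinstance(feature_map, FeatureMap) else np.asarray(feature_map)
    if values.ndim != 2:
        raise ValueError(f"feature map must be 2-D, got shape {values.shape}")
    h, w = values.shape
    if h < 2 * HOG_CELL[0] or w < 2 * HOG_CELL[1] or h % HOG_CELL[0] or w % HOG_CELL[1]:
        raise ValueError(
            f"map size {h}x{w} not compatible with {HOG_CELL} cells / {HOG_BLOCK} blocks"
        )
    return hog(
        values,
        orientations=HOG_ORIENTATIONS,
        pixels_per_cell=HOG_CELL,
        cells_per_block=HOG_BLOCK,
        block_norm="L2",
        feature_vector=True,
    ).astype(np.float64)


def window_descriptor(
    window: FeatureWindow, epsilon: float = DEFAULT_MOTION_EPSILON
) -> np.ndarray:
    """Concatenated [HOG(DMA); HOG(DMH)] descriptor of one window.

    Length 16,200 for the standard 128 x 128 crop size; the DMA half always
    comes first.
    """
    return np.concatenate(
        [hog_descriptor(compute_dma(window)), hog_descriptor(compute_dmh(window, epsilon))]
    )


def windows_from_sequence(
    crops: Sequence[np.ndarray], start_index: int = 0
) -> List[FeatureWindow]:
    """Chop a crop sequence into non-overlapping five-frame windows.

    60 crops yield 12 windows; a trailing remainder shorter than five frames
    produces no window (the caller decides how those frames inherit a
    symbol).  Fewer than five crops yield an empty list.
    """
    n = len(crops) // WINDOW_LENGTH
    windows = []
    for i in range(n):
        lo = i * WINDOW_LENGTH
        windows.append(
            FeatureWindow(
                crops=np.stack(crops[lo : lo + WINDOW_LENGTH]),
                frame_indices=list(range(start_index + lo, start_index + lo + WINDOW_LENGTH)),
            )
        )
    return windows
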