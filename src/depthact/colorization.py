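"""Lossless hue-wheel codec for metric depth maps.

Depth cameras deliver per-pixel camera-to-scene distances that are awkward to
store and impossible to feed to ordinary image tooling.  This module maps
inverse depth (disparity, the quantity that is linear in stereo pixel shift)
onto a six-segment hue circle with 1529 discrete ranks, producing an 8-bit
RGB image in which at least one channel is always saturated, and decodes such
images back to metric depth.

The encoding is exactly invertible: every one of the 1529 integer disparity
levels produces a distinct RGB triple and the four-branch channel-dominance
decoder recovers the level bit-for-bit.  The only loss incurred by a
colorize -> recover round trip is the quantization of disparity onto the
1529-rank scale; the induced depth error at depth ``d`` is bounded by the
local quantization step ``d**2 * (disp_max - disp_min) / 1529``.

Depth value 0 is reserved as the "invalid / no sensor return" sentinel and is
encoded as pure black ``(0, 0, 0)``, a color the hue wheel never produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

#: Number of discrete hue ranks (six RGB ramps of the hue circle).
N_LEVELS = 1529
#: Largest encodable level; level ``N_LEVELS`` would alias level 0 (both pure
#: red), so normalized disparity is clamped to ``[0, MAX_LEVEL]``.
MAX_LEVEL = N_LEVELS - 1

#: Reserved color for the invalid-depth sentinel (never produced by the wheel).
SENTINEL_COLOR: Tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class ColorizationRange:
    """Depth interval the codec represents.

    Parameters
    ----------
    d_min, d_max:
        Shortest / longest representable depth in meters.  Depths outside the
        interval are clamped before encoding.  The defaults (0.5 m, 5.0 m)
        suit an indoor room-scale scene and are fully configurable.
    """

    d_min: float = 0.5
    d_max: float = 5.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d_min) and math.isfinite(self.d_max)):
            raise ValueError("depth bounds must be finite")
        if not 0.0 < self.d_min < self.d_max:
            raise ValueError(
                f"require 0 < d_min < d_max, got d_min={self.d_min}, d_max={self.d_max}"
            )

    @property
    def disp_min(self) -> float:
        """Smallest disparity, ``1 / d_max``."""
        return 1.0 / self.d_max

    @property
    def disp_max(self) -> float:
        """Largest disparity, ``1 / d_min``."""
        return 1.0 / self.d_min

    @property
    def disp_span(self) -> float:
        return self.disp_max - self.disp_min


@dataclass
class DepthFrame:
    """A single depth map: 2-D grid of metric distances, origin top-left.

    ``values`` holds meters as floats; exactly 0 marks an invalid pixel (no
    sensor return), valid pixels are strictly positive.
    """

    values: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"depth frame must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth frame contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("depth values must be >= 0 (0 is the invalid sentinel)")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ColorFrame:
    """An 8-bit RGB image, shape ``(H, W, 3)``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"color frame must have shape (H, W, 3), got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if np.any(self.pixels < 0) or np.any(self.pixels > 255):
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


# ---------------------------------------------------------------------------
# level <-> color
# ---------------------------------------------------------------------------

def _build_encode_lut() -> np.ndarray:
    """Six-segment hue wheel as a (1529, 3) lookup table.

    Segment layout (v = level):
      [0, 255]      (255, v, 0)         red -> yellow
      (255, 510]    (510 - v, 255, 0)   yellow -> green
      (510, 765]    (0, 255, v - 510)   green -> cyan
      (765, 1020]   (0, 1020 - v, 255)  cyan -> blue
      (1020, 1275)  (v - 1020, 0, 255)  blue -> near-magenta
      [1275, 1528]  (255, 0, 1529 - v)  near-magenta -> near-red

    The wheel deliberately skips pure magenta (255, 0, 255): under the
    channel-dominance decoder that triple is claimed by the red-dominant
    branch and would alias level 1274.  With this layout every level decodes
    back to itself.
    """
    v = np.arange(N_LEVELS, dtype=np.int64)
    r = np.zeros(N_LEVELS, dtype=np.int64)
    g = np.zeros(N_LEVELS, dtype=np.int64)
    b = np.zeros(N_LEVELS, dtype=np.int64)

    m = v <= 255
    r[m], g[m] = 255, v[m]
    m = (v > 255) & (v <= 510)
    r[m], g[m] = 510 - v[m], 255
    m = (v > 510) & (v <= 765)
    g[m], b[m] = 255, v[m] - 510
    m = (v > 765) & (v <= 1020)
    g[m], b[m] = 1020 - v[m], 255
    m = (v > 1020) & (v < 1275)
    r[m], b[m] = v[m] - 1020, 255
    m = v >= 1275
    r[m], b[m] = 255, 1529 - v[m]

    return np.stack([r, g, b], axis=-1).astype(np.uint8)


_ENCODE_LUT = _build_encode_lut()


def encode_level(level: int) -> Tuple[int, int, int]:
    """Map a normalized disparity level to its hue-wheel RGB triple.

    Raises ``ValueError`` outside ``[0, 1528]``.
    """
    lv = int(level)
    if lv != level or not 0 <= lv <= MAX_LEVEL:
        raise ValueError(f"level must be an integer in [0, {MAX_LEVEL}], got {level!r}")
    r, g, b = _ENCODE_LUT[lv]
    return int(r), int(g), int(b)


def decode_pixel(p: Tuple[int, int, int]) -> int:
    """Recover the disparity level from an RGB triple.

    Four-branch channel-dominance logic, evaluated in order:

    1. r >= g, r >= b, g >= b  ->  g - b
    2. r >= g, r >= b, g <  b  ->  g - b + 1529
    3. g >= r, g >= b          ->  b - r + 510
    4. b >= g, b >= r          ->  r - g + 1020

    Total on all valid 8-bit triples and the exact inverse of
    :func:`encode_level` on every wheel color.  ``(0, 0, 0)`` is the invalid
    sentinel and is handled by :func:`recover_frame`, not here (branch 1
    would map it to level 0).
    """
    r, g, b = (int(c) for c in p)
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError(f"channel value {c} outside [0, 255]")
    if r >= g and r >= b and g >= b:
        return g - b
    if r >= g and r >= b:  # g < b
        return g - b + N_LEVELS
    if g >= r and g >= b:
        return b - r + 510
    return r - g + 1020


def _decode_levels(pixels: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decode_pixel` over an ``(H, W, 3)`` uint8 array."""
    r = pixels[..., 0].astype(np.int64)
    g = pixels[..., 1].astype(np.int64)
    b = pixels[..., 2].astype(np.int64)
    cond1 = (r >= g) & (r >= b) & (g >= b)
    cond2 = (r >= g) & (r >= b) & (g < b)
    cond3 = (g >= r) & (g >= b)
    return np.select(
        [cond1, cond2, cond3],
        [g - b, g - b + N_LEVELS, b - r + 510],
        default=r - g + 1020,
    )


# ---------------------------------------------------------------------------
# depth <-> level
# ---------------------------------------------------------------------------

def _levels_from_depth(values: np.ndarray, rng: ColorizationRange) -> np.ndarray:
    """Normalized disparity levels for an array of valid (non-sentinel) depths."""
    d = np.clip(values, rng.d_min, rng.d_max)
    disp = 1.0 / d
    x = (disp - rng.disp_min) / rng.disp_span * N_LEVELS
    # round half-up, then clamp the wrap level 1529 down onto 1528
    lv = np.floor(x + 0.5).astype(np.int64)
    return np.clip(lv, 0, MAX_LEVEL)


def depth_to_normal(d: float, rng: ColorizationRange) -> int:
    """Normalize one depth value onto the 1529-rank disparity scale.

    The depth is clamped into ``[d_min, d_max]`` first; the result is an
    integer level in ``[0, 1528]``, non-increasing in ``d``.  Depth 0 is the
    invalid sentinel and is rejected here — frame-level code must route it to
    the sentinel color instead.
    """
    if not math.isfinite(d):
        raise ValueError(f"depth must be finite, got {d!r}")
    if d == 0:
        raise ValueError("depth 0 is the invalid-pixel sentinel; encode as (0, 0, 0)")
    if d < 0:
        raise ValueError(f"depth must be positive, got {d!r}")
    return int(_levels_from_depth(np.asarray([d], dtype=np.float64), rng)[0])


def colorize_frame(frame: DepthFrame, rng: ColorizationRange) -> ColorFrame:
    """Encode a depth frame as a hue-wheel RGB image.

    Sentinel pixels (depth 0) become ``(0, 0, 0)``; every other pixel carries
    a hue color with at least one channel at 255.
    """
    sentinel = frame.values == 0
    # clamp sentinels to a harmless in-range value, overwrite below
    safe = np.where(sentinel, rng.d_max, frame.values)
    levels = _levels_from_depth(safe, rng)
    pixels = _ENCODE_LUT[levels]
    if sentinel.any():
        pixels = pixels.copy()
        pixels[sentinel] = SENTINEL_COLOR
    return ColorFrame(pixels=pixels)


def recover_frame(color: ColorFrame, rng: ColorizationRange) -> DepthFrame:
    """Decode a colorized frame back to metric depth.

    Must be called with the same :class:`ColorizationRange` used for
    encoding.  Sentinel pixels ``(0, 0, 0)`` map back to depth 0.
    """
    levels = _decode_levels(color.pixels)
    depth = N_LEVELS / (N_LEVELS * rng.disp_min + rng.disp_span * levels)
    sentinel = np.all(color.pixels == 0, axis=-1)
    depth = np.where(sentinel, 0.0, depth)
    return DepthFrame(values=depth)


def mean_squared_error(I, K) -> float:
    """Per-pixel mean squared error between two depth frames (m² units).

    Symmetric, non-negative, zero iff the frames are identical.
    """
    a = np.asarray(I.values if isinstance(I, DepthFrame) else I, dtype=np.float64)
    b = np.asarray(K.values if isinstance(K, DepthFrame) else K, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))
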