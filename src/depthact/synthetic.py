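"""Seeded generator of labeled synthetic depth recordings.

Emulates the structure of a 1 fps indoor depth recording of a single
resident: a static planar background whose depth grows from the top of the
frame to the bottom, plus one person rendered as an elliptical blob that
sits a configurable distance nearer to the camera.  Each of the four static
postures has its own blob geometry (standing tall and narrow, sitting
medium, lying wide and low, seated medium with a wheelchair block under
it); Transition frames linearly interpolate between the neighboring
postures, which also gives them the inter-frame motion the DMH map keys on.

The blobs are deliberately geometric rather than human-shaped: every
downstream stage consumes only depth statistics of crops, so
action-specific aspect ratios and depth offsets exercise the full pipeline
while keeping rendering trivial and fully reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .actions import ActionLabel
from .colorization import ColorizationRange, DepthFrame, colorize_frame
from .detection import BoundingBox
from .features import (
    CROP_SIZE,
    DEFAULT_MOTION_EPSILON,
    WINDOW_LENGTH,
    crop_resize_recover,
    FeatureWindow,
    window_descriptor,
)
from .hmm import LabeledDescriptors, TrainingDatasets


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, depth range, and noise of the synthetic room.

    The background is a vertical depth gradient from ``bg_near`` (top row)
    to ``bg_far`` (bottom row), both strictly inside ``(d_min, d_max)``.
    ``noise_sd`` is the per-pixel Gaussian depth noise in meters (a small
    positive value mimics stereo depth jitter).
    """

    width: int = 320
    height: int = 240
    d_min: float = 0.5
    d_max: float = 5.0
    bg_near: float = 2.5
    bg_far: float = 4.5
    noise_sd: float = 0.01
    fps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.d_min < self.bg_near <= self.bg_far < self.d_max):
            raise ValueError("background depths must lie strictly inside (d_min, d_max)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32x32 px")

    @property
    def colorization_range(self) -> ColorizationRange:
        return ColorizationRange(d_min=self.d_min, d_max=self.d_max)


@dataclass(frozen=True)
class Pose:
    """Person blob parameters: ellipse center (frame fractions), axes (px),
    how far in front of the background the body sits (m), and a 0..1
    wheelchair factor scaling the block drawn under the ellipse."""

    cx: float
    cy: float
    rx: float
    ry: float
    depth_offset: float
    chair: float = 0.0

    def interpolate(self, other: "Pose", u: float) -> "Pose":
        """Linear blend ``(1-u)*self + u*other`` of every parameter."""
        w = float(np.clip(u, 0.0, 1.0))
        return Pose(
            cx=self.cx + w * (other.cx - self.cx),
            cy=self.cy + w * (other.cy - self.cy),
            rx=self.rx + w * (other.rx - self.rx),
            ry=self.ry + w * (other.ry - self.ry),
            depth_offset=self.depth_offset + w * (other.depth_offset - self.depth_offset),
            chair=self.chair + w * (other.chair - self.chair),
        )


#: Default blob geometry per static posture (320 x 240 scene).
DEFAULT_POSES: Dict[ActionLabel, Pose] = {
    ActionLabel.STANDING: Pose(cx=0.50, cy=0.45, rx=18.0, ry=70.0, depth_offset=1.2),
    ActionLabel.SITTING: Pose(cx=0.50, cy=0.58, rx=30.0, ry=40.0, depth_offset=1.0),
    ActionLabel.LYING: Pose(cx=0.50, cy=0.72, rx=75.0, ry=20.0, depth_offset=0.8),
    ActionLabel.SEATED: Pose(cx=0.50, cy=0.55, rx=26.0, ry=34.0, depth_offset=1.1, chair=1.0),
}


@dataclass
class ScriptSegment:
    """One scripted stretch of a recording: an action held for >= 5 frames."""

    action: ActionLabel
    duration: int

    def __post_init__(self) -> None:
        if self.duration < WINDOW_LENGTH:
            raise ValueError(f"segment duration must be >= {WINDOW_LENGTH} frames")


@dataclass
class Recording:
    """Frames, per-frame ground-truth boxes (None = empty scene), labels."""

    frames: List[DepthFrame]
    boxes: List[Optional[BoundingBox]]
    labels: np.ndarray
    config: SceneConfig


def background_frame(config: SceneConfig) -> DepthFrame:
    """The noiseless empty-scene background plane."""
    rows = np.linspace(config.bg_near, config.bg_far, config.height)
    return DepthFrame(values=np.repeat(rows[:, None], config.width, axis=1))


def _person_mask(config: SceneConfig, pose: Pose) -> np.ndarray:
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    cx, cy = pose.cx * config.width, pose.cy * config.height
    mask = ((xx - cx) / pose.rx) ** 2 + ((yy - cy) / pose.ry) ** 2 <= 1.0
    if pose.chair > 1e-3:
        # wheelchair: a block below the torso ellipse, grown with the factor
        half_w = pose.rx * (1.0 + 0.6 * pose.chair)
        top = cy + 0.3 * pose.ry
        bot = min(cy + pose.ry + 18.0 * pose.chair, config.height - 1)
        mask |= (np.abs(xx - cx) <= half_w) & (yy >= top) & (yy <= bot)
    return mask


def render_frame(
    config: SceneConfig,
    pose: Optional[Pose],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[DepthFrame, Optional[BoundingBox]]:
    """Render one frame: background plane plus (optionally) the person blob.

    The person sits ``pose.depth_offset`` meters in front of the local
    background; Gaussian depth noise of ``config.noise_sd`` is added when an
    ``rng`` is supplied and the scene is noisy.  Returns the frame and the
    tight ground-truth box of the person pixels (None when no person).
    """
    depth = background_frame(config).values.copy()
    box: Optional[BoundingBox] = None
    if pose is not None:
        cx, cy = pose.cx * config.width, pose.cy * config.height
        if not (pose.rx <= cx <= config.width - pose.rx and pose.ry * 0.5 <= cy):
            raise ValueError(f"pose centered at ({cx:.0f}, {cy:.0f}) extends outside the frame")
        mask = _person_mask(config, pose)
        depth[mask] -= pose.depth_offset
        ys, xs = np.nonzero(mask)
        box = BoundingBox(
            x0=int(xs.min()), y0=int(ys.min()), x1=int(xs.max()) + 1, y1=int(ys.max()) + 1
        )
    if rng is not None and config.noise_sd > 0:
        depth = depth + rng.normal(0.0, config.noise_sd, depth.shape)
    depth = np.clip(depth, config.d_min + 1e-6, config.d_max - 1e-6)
    return DepthFrame(values=depth), box


def _segment_poses(script: Sequence[ScriptSegment]) -> List[List[Pose]]:
    """Per-frame pose track for every segment; Transition interpolates."""
    poses_by_segment: List[List[Pose]] = []
    for i, seg in enumerate(script):
        if seg.action is not ActionLabel.TRANSITION:
            poses_by_segment.append([DEFAULT_POSES[seg.action]] * seg.duration)
            continue
        prev_action = next(
            (script[j].action for j in range(i - 1, -1, -1)
             if script[j].action is not ActionLabel.TRANSITION),
            ActionLabel.STANDING,
        )
        next_action = next(
            (script[j].action for j in range(i + 1, len(script))
             if script[j].action is not ActionLabel.TRANSITION),
            ActionLabel.SITTING,
        )
        a, b = DEFAULT_POSES[prev_action], DEFAULT_POSES[next_action]
        us = np.linspace(0.0, 1.0, seg.duration + 2)[1:-1]
        poses_by_segment.append([a.interpolate(b, float(u)) for u in us])
    return poses_by_segment


def generate_recording(config: SceneConfig, script: Sequence[ScriptSegment]) -> Recording:
    """Render a scripted recording, fully reproducible from ``config.seed``.

    One frame per scripted frame; Transition segments sweep the pose
    linearly from the previous posture to the next; labels align 1:1 with
    frames.
    """
    if not script:
        raise ValueError("script must contain at least one segment")
    rng = np.random.default_rng(config.seed)
    frames: List[DepthFrame] = []
    boxes: List[Optional[BoundingBox]] = []
    labels: List[int] = []
    for seg, poses in zip(script, _segment_poses(script)):
        for pose in poses:
            frame, box = render_frame(config, pose, rng)
            frames.append(frame)
            boxes.append(box)
            labels.append(int(seg.action))
    return Recording(frames=frames, boxes=boxes, labels=np.asarray(labels), config=config)


def generate_action_script(
    rng: np.random.Generator,
    n_static_segments: int = 6,
    static_duration: int = 30,
    transition_duration: int = 10,
) -> List[ScriptSegment]:
    """A realistic script: static postures joined by Transition stretches.

    Durations default to multiples of the five-frame feature window so
    segment boundaries align with windows, as they do when features fire
    once every five frames from the start of a recording.
    """
    statics = [a for a in ActionLabel if a is not ActionLabel.TRANSITION]
    script: List[ScriptSegment] = []
    prev = None
    for _ in range(n_static_segments):
        choices = [a for a in statics if a != prev]
        action = choices[int(rng.integers(len(choices)))]
        if prev is not None:
            script.append(ScriptSegment(ActionLabel.TRANSITION, transition_duration))
        script.append(ScriptSegment(action, static_duration))
        prev = action
    return script


# ---------------------------------------------------------------------------
# descriptor dataset generation
# ---------------------------------------------------------------------------

def _sequence_window(
    config: SceneConfig,
    state: ActionLabel,
    rng: np.random.Generator,
    epsilon: float,
    crop_size: int,
) -> np.ndarray:
    """Descriptor of one five-frame clip of the given action."""
    crange = config.colorization_range
    if state is ActionLabel.TRANSITION:
        statics = [a for a in ActionLabel if a is not ActionLabel.TRANSITION]
        i, j = rng.choice(len(statics), size=2, replace=False)
        a, b = DEFAULT_POSES[statics[i]], DEFAULT_POSES[statics[j]]
        u0 = rng.uniform(0.0, 0.5)
        us = np.linspace(u0, u0 + 0.5, WINDOW_LENGTH)
        poses = [a.interpolate(b, float(u)) for u in us]
    else:
        base = DEFAULT_POSES[state]
        jitter = replace(
            base,
            cx=base.cx + rng.uniform(-0.03, 0.03),
            cy=base.cy + rng.uniform(-0.02, 0.02),
        )
        poses = [jitter] * WINDOW_LENGTH
    crops = []
    for pose in poses:
        frame, box = render_frame(config, pose, rng)
        color = colorize_frame(frame, crange)
        crops.append(crop_resize_recover(color, box, crange, size=crop_size))
    return window_descriptor(FeatureWindow(crops=np.stack(crops)), epsilon)


def generate_datasets(
    config: SceneConfig,
    per_state_counts: Tuple[int, int] = (900, 100),
    epsilon: float = DEFAULT_MOTION_EPSILON,
    crop_size: int = CROP_SIZE,
) -> TrainingDatasets:
    """Class-balanced descriptor datasets for assigner and emission training.

    ``per_state_counts = (n_train, n_emission)`` sequences per state
    (900/100 at full scale; scale down freely for fast tests).  Each
    sequence is five continuous rendered frames.  The two sets draw from
    disjoint seeded streams, so they never share a rendered frame.
    """
    n_train, n_emission = per_state_counts
    ss = np.random.SeedSequence(config.seed)
    train_rng, emission_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    parts = []
    for count, rng in ((n_train, train_rng), (n_emission, emission_rng)):
        X, y = [], []
        for state in ActionLabel:
            for _ in range(count):
                X.append(_sequence_window(config, state, rng, epsilon, crop_size))
                y.append(int(state))
        parts.append(LabeledDescriptors(X=np.stack(X), y=np.asarray(y)))
    return TrainingDatasets(train=parts[0], emission=parts[1])


def random_depth_map(
    shape: Tuple[int, int],
    crange: ColorizationRange,
    rng: np.random.Generator,
    smoothness: float = 6.0,
) -> DepthFrame:
    """A smooth random depth surface spanning the full codec range.

    Gaussian-filtered white noise rescaled onto ``[d_min, d_max]`` — the
    kind of gently varying surface an indoor depth camera sees, used for
    codec round-trip audits.
    """
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness)
    lo, hi = smooth.min(), smooth.max()
    unit = (smooth - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)
    return DepthFrame(values=crange.d_min + unit * (crange.d_max - crange.d_min))
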