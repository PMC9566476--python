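"""Detect the person in a synthetic depth scene through the codec.

Renders a standing person into a room scene, colorizes the frame, and runs
the depth-difference oracle detector on the colorized image, comparing its
box against the generator's ground truth.
"""

from depthact import (
    ActionLabel,
    DepthOracleDetector,
    SceneConfig,
    background_frame,
    colorize_frame,
    render_frame,
    select_primary_box,
)
from depthact.synthetic import DEFAULT_POSES

config = SceneConfig(seed=3)
background = background_frame(config)
frame, truth_box = render_frame(config, DEFAULT_POSES[ActionLabel.STANDING])

color = colorize_frame(frame, config.colorization_range)
detector = DepthOracleDetector(background=background,
                               colorization_range=config.colorization_range)
box = select_primary_box(detector.detect(color))

print(f"ground truth box: ({truth_box.x0},{truth_box.y0})-({truth_box.x1},{truth_box.y1})")
print(f"detected box:     ({box.x0},{box.y0})-({box.x1},{box.y1})  area={box.area} px^2")
print(f"IoU: {box.iou(truth_box):.3f}")
# IoU near 1.0: on synthetic scenes the oracle recovers the person exactly,
# standing in for a trained person detector in tests.
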