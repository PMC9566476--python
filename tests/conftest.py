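"""Shared fixtures: a seeded scene, small rendered datasets, label scripts.

Dataset fixtures are session-scoped because rendering descriptor sets is
the expensive part of the suite; every test that needs trained assigners
shares one small class-balanced set.
"""

from __future__ import annotations

import numpy as np
import pytest

from depthact import (
    ColorizationRange,
    SceneConfig,
    generate_action_script,
    generate_datasets,
)


@pytest.fixture(scope="session")
def crange() -> ColorizationRange:
    return ColorizationRange(d_min=0.5, d_max=5.0)


@pytest.fixture(scope="session")
def scene_config() -> SceneConfig:
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def small_datasets(scene_config):
    """12 training / 6 emission sequences per state — fast but separable."""
    return generate_datasets(scene_config, per_state_counts=(12, 6))


@pytest.fixture(scope="session")
def transition_labels() -> np.ndarray:
    """Frame labels of a long scripted stay, for transition-matrix counts."""
    script = generate_action_script(np.random.default_rng(42), n_static_segments=20)
    return np.concatenate([[int(s.action)] * s.duration for s in script])
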