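"""Shared fixtures: synthetic scenes are expensive, so the two standard
scenes (a small 3-neuron scene and the full 8-neuron benchmark scene) are
built once per session and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from speconn.detection import run_detection
from speconn.synth import SceneConfig, build_scene

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


SMALL_SCENE = dict(
    size_um=(26.0, 26.0, 13.0), n_neurons=3, n_external_axons=8,
    soma_radius_um=(4.0, 4.8), n_synapses=25,
    n_distractor_contact=3, n_distractor_unlabeled=3,
    dendrite_total_um=220.0, n_color_clusters=5, fiducial_n_blobs=120,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 26x26x13 um scene with 3 neurons and 25 planted synapses (seed 11)."""
    return build_scene(SceneConfig(seed=11, **SMALL_SCENE))


@pytest.fixture(scope="session")
def small_detection(small_scene):
    return run_detection(small_scene.grid, small_scene.skeletons)


@pytest.fixture(scope="session")
def default_scene():
    """The benchmark scene: 8 neurons, 30 external axons, 150 planted
    synapses, 15 + 15 distractors, default noise, seed 7."""
    return build_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def default_detection(default_scene):
    return run_detection(default_scene.grid, default_scene.skeletons)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
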