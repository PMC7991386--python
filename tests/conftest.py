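import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from drgcal import DetectionParams, detect_neurons
from drgcal.synthgen import SynthConfig, render_recording


@pytest.fixture(scope="session")
def small_recording():
    """A 256×256 synthetic recording with 10 neurons, standard noise, no motion."""
    cfg = SynthConfig(seed=11, field_size=(256, 256), n_neurons=10)
    stack, truth = render_recording(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def detection_recording():
    """The detection-benchmark recording: 512×512, 1000 frames, 30 neurons.

    Duration is capped at 20 s (1000 frames at 50 Hz) covering the first two
    pressure steps, so the class mix is restricted to muscular archetypes
    that fire within that span.
    """
    from drgcal.classify import AfferentClass

    cfg = SynthConfig(
        seed=21,
        field_size=(512, 512),
        n_neurons=30,
        duration=20.0,
        class_mix={AfferentClass.LT_MUSCULAR: 0.5, AfferentClass.HT_MUSCULAR: 0.5},
    )
    stack, truth = render_recording(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def detection_result(detection_recording):
    cfg, stack, truth = detection_recording
    params = DetectionParams(expected_neurons=cfg.n_neurons)
    label_map, rois, log = detect_neurons(stack, params)
    return label_map, rois, log


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
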