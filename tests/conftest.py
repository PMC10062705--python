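import numpy as np
import pytest

from budcount.core import Box, Detection, FrameDetections
from budcount.simulate import SceneConfig
from budcount.tracking import TrackerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230330)


@pytest.fixture
def cfg():
    """Default tracker configuration (960x608 image, zones at 0.25/0.75)."""
    return TrackerConfig()


@pytest.fixture
def small_scene_cfg():
    """A short scene for fast end-to-end tests, noise off."""
    return SceneConfig(n_frames=120, seed=7)


def detections_at(frame, *centers, w=40.0, h=60.0, conf=0.9):
    """One frame of detections at the given (cx, cy) centers."""
    dets = [
        Detection(Box.from_center(cx, cy, w, h), conf, frame) for cx, cy in centers
    ]
    return FrameDetections(frame, dets)


@pytest.fixture
def make_frame():
    return detections_at
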