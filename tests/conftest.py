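import numpy as np
import pytest

from vogkit.core.settings import PipelineSettings, TrackerSettings
from vogkit.synthetic import GlintSpec, SyntheticScene


@pytest.fixture
def scene():
    """Default synthetic scene: pupil + iris texture + one glint."""
    return SyntheticScene()


@pytest.fixture
def quiet_scene():
    """Scene without reflections; used by torsion tests so no bright spot
    sits inside the iris annulus."""
    return SyntheticScene(glints=())


@pytest.fixture
def settings():
    return PipelineSettings()


@pytest.fixture
def tracker_settings():
    return TrackerSettings()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disk(shape, center, radius, value=10, background=200):
    """Hard-edged dark disk test image (uint8)."""
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, background, dtype=np.uint8)
    img[(xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius ** 2] = value
    return img


def gaussian_spot(shape, center, amplitude, sigma, background=0):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    g = np.exp(-((xs - center[0]) ** 2 + (ys - center[1]) ** 2) / (2 * sigma ** 2))
    img = background * (1 - g) + amplitude * g
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
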