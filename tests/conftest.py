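import numpy as np
import pytest

from preyevo import (
    FULL_BOX,
    BackgroundSpec,
    TargetImage,
    VisualSystem,
    generate_background,
    lab_to_srgb,
)
from preyevo.genome_pattern import _ellipse_mask


@pytest.fixture
def vs() -> VisualSystem:
    return VisualSystem()


@pytest.fixture
def dichromat() -> VisualSystem:
    return VisualSystem(
        receptor_matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        weber=np.array([0.1, 0.1]),
        weber_lum=0.1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def full_box():
    return FULL_BOX


@pytest.fixture
def small_background() -> np.ndarray:
    return generate_background(BackgroundSpec(size=(128, 128), seed=42))


def uniform_background(lab, size=(64, 64)) -> np.ndarray:
    """Single-colour background from a Lab triple."""
    rgb = lab_to_srgb(np.asarray(lab, float))
    return np.tile(rgb, (size[1], size[0], 1)).astype(np.uint8)


def solid_target(lab, size=(64, 48), target_id="solid") -> TargetImage:
    """Oval target filled with one Lab colour."""
    w, h = size
    mask = _ellipse_mask(w, h)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[mask] = lab_to_srgb(np.asarray(lab, float))
    return TargetImage(rgb, mask, target_id)


@pytest.fixture
def uniform_bg_fn():
    return uniform_background


@pytest.fixture
def solid_target_fn():
    return solid_target
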