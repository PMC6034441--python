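import numpy as np
import pytest

from fieldvision.ps_core import LightSet


@pytest.fixture
def lights3() -> LightSet:
    """Standard three-light rig: two x-axis lights and one y-axis light."""
    return LightSet([(0.5, 0.0), (-0.5, 0.0), (0.0, 0.5)])


@pytest.fixture
def lights4() -> LightSet:
    """Four-light rig with symmetric x and y pairs."""
    return LightSet([(0.5, 0.0), (-0.5, 0.0), (0.0, 0.5), (0.0, -0.5)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def angular_error(n_est: np.ndarray, n_true: np.ndarray) -> np.ndarray:
    """Per-pixel angle in radians between two unit-normal rasters."""
    dots = np.clip(np.sum(n_est * n_true, axis=-1), -1.0, 1.0)
    return np.arccos(dots)
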