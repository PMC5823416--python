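import numpy as np
import pytest

from pyloruskit.csd import VROFMask
from pyloruskit.synthetic import SyntheticConfig


def full_mask(shape) -> VROFMask:
    m = np.ones(shape, dtype=bool)
    return VROFMask(mask=m, n_valid=int(m.size), fallback=False)


def mask_from(mask: np.ndarray) -> VROFMask:
    mask = np.asarray(mask, dtype=bool)
    return VROFMask(mask=mask, n_valid=int(mask.sum()), fallback=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_cfg():
    """Fast, small-frame configuration for unit tests."""
    return SyntheticConfig(
        n_frames=12,
        boundary_frame=6,
        frame_width=64,
        frame_height=60,
        disturbance_rate=0.0,
        seed=11,
    )
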