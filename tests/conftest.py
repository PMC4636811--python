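import numpy as np
import pytest

from mammocalc import GrayImage, PipelineConfig


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20150894)


def random_image(seed: int, shape=(32, 32), hi=256, bit_depth=8) -> GrayImage:
    """Seeded random-integer image used by the oracle-equivalence tests."""
    r = np.random.default_rng(seed)
    return GrayImage(
        r.integers(0, hi, size=shape).astype(float), bit_depth_hint=bit_depth
    )


@pytest.fixture
def spike_image():
    """Flat field 50 with one interior pixel raised to 250."""
    px = np.full((64, 64), 50.0)
    px[31, 33] = 250.0
    return GrayImage(px)
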