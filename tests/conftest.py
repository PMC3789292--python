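import numpy as np
import pytest

from mammocad import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flat_image(value: float = 100.0, shape=(64, 64), bit_depth: int = 8) -> GrayImage:
    return GrayImage(pixels=np.full(shape, float(value)), bit_depth=bit_depth)


def random_u8(rng: np.random.Generator, shape=(64, 64)) -> GrayImage:
    return GrayImage(pixels=rng.integers(0, 256, size=shape).astype(np.int64), bit_depth=8)
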