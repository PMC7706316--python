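import numpy as np
import pytest

from tasselgen import fixtures as fx


@pytest.fixture(scope="session")
def tassel_params():
    return fx.TasselParams()


@pytest.fixture(scope="session")
def small_tassel_set():
    """20 tassel images + masks at 64×64 for evaluation tests."""
    imgs, masks = fx.make_tassel_set(20, fx.TasselParams(resolution=64), seed=50)
    return imgs, masks


@pytest.fixture(scope="session")
def small_sky_set():
    return fx.make_sky_set(10, fx.SkyParams(resolution=64), seed=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return (a & b).sum() / (a | b).sum()
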