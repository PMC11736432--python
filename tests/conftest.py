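import numpy as np
import pytest

from wirenet.geometry import SpatialLayout, place_on_circle
from wirenet.wiring_cost import SparseNet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_net(n: int, density: float, rng: np.random.Generator, dim: int = 2) -> SparseNet:
    """Random sparse net over random coordinates; weights ~ N(0,1) on the mask."""
    coords = rng.uniform(-1.0, 1.0, size=(n, dim))
    layout = SpatialLayout(coords)
    mask = (rng.uniform(size=(n, n)) < density).astype(float)
    weights = rng.standard_normal((n, n)) * mask
    return SparseNet(mask, weights, layout)


@pytest.fixture
def small_net(rng):
    return random_net(8, 0.4, rng)


@pytest.fixture
def circle_net(rng):
    layout = place_on_circle(12, radius=1.0, seed=3, mode="equally_spaced")
    mask = (rng.uniform(size=(12, 12)) < 0.3).astype(float)
    np.fill_diagonal(mask, 0.0)
    weights = rng.standard_normal((12, 12)) * mask
    return SparseNet(mask, weights, layout)
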