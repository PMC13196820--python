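import numpy as np
import pytest

from pdmdiff.shape_io import PointSet, ShapeDataset
from pdmdiff.synthetic import SyntheticConfig, generate_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """Two-class 32-point population with a known localized effect."""
    cfg = SyntheticConfig(
        n_points=32,
        n_per_class={"healthy": 40, "AD": 40},
        effect_indices=tuple(range(4)),
        effect_magnitude=-0.3,
        noise_sd=0.02,
        seed=11,
    )
    return generate_population(cfg)


@pytest.fixture()
def random_dataset(rng):
    return ShapeDataset(rng.standard_normal((10, 8, 3)))


@pytest.fixture()
def random_shape(rng):
    return PointSet(rng.standard_normal((8, 3)))
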