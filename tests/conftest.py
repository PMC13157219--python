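import numpy as np
import pytest

from plantfill.cloud import PointCloud, ifps_indices, normalize
from plantfill.synthetic import PlantSpec, generate_plant


@pytest.fixture(scope="session")
def plant():
    """A deterministic mid-size synthetic plant with organ labels."""
    return generate_plant(PlantSpec(seed=7, n_leaves=4, points_total=6000))


@pytest.fixture(scope="session")
def plant_2048(plant):
    """The session plant downsampled to the full-scale input size, normalized."""
    sub = plant.select(ifps_indices(plant.points, 2048, seed=0))
    norm, _ = normalize(sub)
    return norm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, scale=1.0):
    return PointCloud(rng.uniform(-scale, scale, (n, 3)))
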