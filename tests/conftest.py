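import numpy as np
import pytest

from phenopot3d import PointCloud
from phenopot3d.synthetic import (curved_5leaf_spec, generate_plant,
                                  straight_3leaf_spec, suggested_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform(-0.1, 0.1, (500, 3)))


@pytest.fixture(scope="session")
def straight_plant():
    """Straight-stem 3-leaf synthetic plant with its truth and scaled config."""
    spec = straight_3leaf_spec(7)
    cloud, truth = generate_plant(spec)
    return cloud, truth, suggested_config(spec)


@pytest.fixture(scope="session")
def curved_plant():
    spec = curved_5leaf_spec(11)
    cloud, truth = generate_plant(spec)
    return cloud, truth, suggested_config(spec)


@pytest.fixture(scope="session")
def straight_result(straight_plant):
    from phenopot3d.pipeline import run_pipeline
    cloud, truth, config = straight_plant
    return run_pipeline(cloud, config), truth


@pytest.fixture(scope="session")
def curved_result(curved_plant):
    from phenopot3d.pipeline import run_pipeline
    cloud, truth, config = curved_plant
    return run_pipeline(cloud, config), truth
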