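import numpy as np
import pytest

from fcdmap import BoldSeries, SimConfig


@pytest.fixture(scope="session")
def tiny_config():
    """A fast 12^3 cohort at shortened scan length (2 + 2 subjects)."""
    return SimConfig(grid_shape=(12, 12, 12), n_volumes=60, n_per_group=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(data, voxel_size=3.0, tr=2.0):
    """BoldSeries with an isotropic, origin-centered affine."""
    data = np.asarray(data)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(data.shape[:3]) - 1) / 2.0
    return BoldSeries(data=data, affine=affine, tr=tr)


@pytest.fixture()
def random_series(rng):
    """8^3 white-noise series, 40 volumes, 3 mm voxels."""
    return make_series(rng.standard_normal((8, 8, 8, 40)))
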