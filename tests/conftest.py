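import numpy as np
import pytest

from copulafc import RegionActivity


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_pair(rng):
    """Two univariate samples with true correlation 0.5, n=2000."""
    cov = [[1.0, 0.5], [0.5, 1.0]]
    z = rng.multivariate_normal([0, 0], cov, size=2000).T
    return z[:1], z[1:]


def make_region(rng, n_voxels=10, n_timepoints=80, region_id="r"):
    return RegionActivity(rng.normal(size=(n_voxels, n_timepoints)), region_id=region_id)


@pytest.fixture
def region_pair(rng):
    return make_region(rng, 10, 80, "x"), make_region(rng, 12, 80, "y")
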