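import numpy as np
import pytest

from mousebrainsim import make_connectome, make_tracer_set


@pytest.fixture(scope="session")
def small_connectome():
    return make_connectome(10, seed=3)


@pytest.fixture(scope="session")
def tracer_fixture():
    """(experiment set, annotation volume, ground truth) for builder tests."""
    return make_tracer_set(n_regions=3, seed=7, experiments_per_source=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
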