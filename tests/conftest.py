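import numpy as np
import pytest
from hypothesis import settings

import bayesmech as bm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Covariance of the worked 3x3 example, frozen from the adjugate oracle
#: Sigma = adj(Pi) / det(Pi) with det(Pi) = 4.
EXAMPLE_SIGMA = np.array(
    [[0.75, -0.5, 0.25], [-0.5, 1.0, -0.5], [0.25, -0.5, 0.75]]
)


@pytest.fixture(scope="session")
def example_density():
    return bm.get_preset("example_2_2")


@pytest.fixture(scope="session")
def example_sync(example_density):
    return bm.build_sync_map(example_density)


@pytest.fixture(scope="session")
def remark_model():
    return bm.get_preset("remark_3_2")


@pytest.fixture(scope="session")
def degenerate_density():
    return bm.get_preset("fig2_degenerate")


def random_blanket_density(seed, d_eta=2, d_s=1, d_a=1, d_mu=3):
    """Seeded random fixture with d_b <= d_mu (sync map generically exists)."""
    part = bm.BlanketPartition(d_eta, d_s, d_a, d_mu)
    return bm.sample_blanket_precision(part, seed=seed, scale=1.0)


@pytest.fixture
def random_density_factory():
    return random_blanket_density
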