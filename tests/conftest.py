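import numpy as np
import pytest

from wmnet import CohortConfig, ConnectivityMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A miniature three-group cohort for fast structural checks."""
    return generate_cohort(
        CohortConfig(n_per_group=4, n_regions=30, seed=11)
    )


@pytest.fixture
def star5():
    """5-node star with unit weights, node 0 at the center."""
    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = 1.0
    return ConnectivityMatrix(W)


@pytest.fixture
def k4():
    """Complete graph on 4 nodes with unit weights."""
    return ConnectivityMatrix(np.ones((4, 4)) - np.eye(4))
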