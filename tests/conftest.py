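import numpy as np
import pytest

from sysseg import ConnectivityMatrix, NetworkPartition
from sysseg.io import load_bundled_partition


@pytest.fixture(scope="session")
def yeo17_toy() -> NetworkPartition:
    return load_bundled_partition("yeo17_toy")


@pytest.fixture(scope="session")
def yeo7_toy() -> NetworkPartition:
    return load_bundled_partition("yeo7_toy")


@pytest.fixture
def two_block_partition() -> NetworkPartition:
    """Two associative networks of two ROIs each."""
    return NetworkPartition(
        roi_to_network={"r1": "A", "r2": "A", "r3": "B", "r4": "B"},
        network_flags={"A": True, "B": True},
    )


@pytest.fixture
def worked_matrix() -> ConnectivityMatrix:
    """4-ROI fixture: within edges 0.6 and 0.4, all between edges 0.1.

    Hand arithmetic: W = (0.6 + 0.4)/2 = 0.5, B = 0.1, SyS = 0.8.
    """
    z = np.array(
        [
            [0.0, 0.6, 0.1, 0.1],
            [0.6, 0.0, 0.1, 0.1],
            [0.1, 0.1, 0.0, 0.4],
            [0.1, 0.1, 0.4, 0.0],
        ]
    )
    return ConnectivityMatrix(z, ["r1", "r2", "r3", "r4"])


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(scale=0.4, size=(n, n))
    z = (a + a.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z
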