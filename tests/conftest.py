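import numpy as np
import pytest

from phenonet.examples import toy_block
from phenonet.temporal_data import build_network, copresence_matrix


@pytest.fixture(scope="session")
def worked_block():
    """The 3x3-actor, 6-day worked-example block."""
    return toy_block()


@pytest.fixture(scope="session")
def worked_network(worked_block):
    return build_network(worked_block)


@pytest.fixture(scope="session")
def worked_copresence(worked_block, worked_network):
    return copresence_matrix(worked_block, worked_network)


def random_network_matrix(rng: np.random.Generator, max_side: int = 50,
                          fill: float = 0.3) -> np.ndarray:
    """Random binary incidence with no empty rows/columns."""
    while True:
        R = rng.integers(2, max_side + 1)
        C = rng.integers(2, max_side + 1)
        mat = (rng.random((R, C)) < fill).astype(np.int8)
        mat = mat[mat.sum(axis=1) > 0][:, mat.sum(axis=0) > 0]
        if mat.size and mat.shape[0] >= 2 and mat.shape[1] >= 2:
            return mat
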