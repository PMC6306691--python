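import numpy as np
import pytest

from alffband.synthetic import VoxelGrid, BoldDataset, gen_parcellation


@pytest.fixture(scope="session")
def small_parc():
    """A 20-region parcellation on a 12x12x10 grid (fast fixture)."""
    return gen_parcellation(dims=(12, 12, 10), n_regions=20, seed=3)


@pytest.fixture(scope="session")
def default_parc():
    """The default 116-region parcellation on the full desk-scale grid."""
    return gen_parcellation(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_dataset(data: np.ndarray, tr: float = 2.0) -> BoldDataset:
    grid = VoxelGrid(dims=data.shape[:3])
    return BoldDataset(data=np.asarray(data, dtype=float), tr_seconds=tr, grid=grid)
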