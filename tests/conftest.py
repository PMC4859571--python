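import numpy as np
import pytest

from voxscreen.atlas_io import RoiSpec, build_matrix, select_roi_pair
from voxscreen.synthetic_atlas import AtlasConfig, generate_atlas

SMALL_GRID = (21, 10, 9)
NULL_GRID = (14, 5, 3)  # tiny grid for many-seed null simulations


@pytest.fixture(scope="session")
def small_config():
    """Planted atlas small enough for per-test use: 200 genes, 5+5 planted."""
    return AtlasConfig(
        grid_shape=SMALL_GRID, n_genes=200, n_posterior=5, n_anterior=5, seed=11
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return generate_atlas(small_config)


@pytest.fixture(scope="session")
def small_screen(small_atlas):
    """Matrix + ROI pair over the small planted atlas."""
    volumes, annotation, truth = small_atlas
    matrix = build_matrix(volumes, annotation)
    pair = select_roi_pair(
        matrix,
        RoiSpec("vulnerable", frozenset({"II", "III"})),
        RoiSpec("resistant", frozenset({"X"})),
    )
    return matrix, pair, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
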