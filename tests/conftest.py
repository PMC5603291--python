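import numpy as np
import pytest

from alphaem.experiment import ExperimentPlan, prepare_study
from alphaem.projector import Geometry, build_system_matrix


MASTER_SEED = 123


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def study_ctx():
    """Calibrated default phantom + full 128x128 system matrix, built once."""
    return prepare_study(ExperimentPlan(master_seed=MASTER_SEED))


@pytest.fixture(scope="session")
def system_matrix(study_ctx):
    return study_ctx.system_matrix


@pytest.fixture(scope="session")
def small_geometry():
    """An 8x8-grid geometry for cheap exact projector checks."""
    return Geometry(n_views=4, n_bins=8, angular_range=360.0, center=(3.5, 3.5))


@pytest.fixture(scope="session")
def small_system_matrix(small_geometry):
    return build_system_matrix(small_geometry, grid_size=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
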