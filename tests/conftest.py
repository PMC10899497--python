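import numpy as np
import pytest

from tmstarget import efield as ef
from tmstarget import headgeom as hg
from tmstarget import synth


@pytest.fixture(scope="session")
def default_head_mask():
    """Adult-sized spherical head (scalp 92 mm, cortex 78 mm) with shell mask."""
    return synth.make_spherical_head()


@pytest.fixture(scope="session")
def head(default_head_mask):
    return default_head_mask[0]


@pytest.fixture(scope="session")
def mask(default_head_mask):
    return default_head_mask[1]


@pytest.fixture(scope="session")
def mdd_space():
    """Frontal CPC search space (29 x 17 grid at step 0.01)."""
    return hg.build_search_space((0.15, 0.43), (0.27, 0.43), 0.01)


@pytest.fixture(scope="session")
def mdd_fields(head, mask, mdd_space):
    return ef.search_space_fields(head, mask, mdd_space)


@pytest.fixture(scope="session")
def smoother(mask):
    cfg = synth.SyntheticCohortConfig()
    return synth.build_smoother(mask, cfg.local_smooth_mm)


@pytest.fixture(scope="session")
def small_head_mask():
    """Coarse head for cheap tests (few hundred mask voxels)."""
    return synth.make_spherical_head(subdiv=3, grid_mm=10.0, shell_mm=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
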