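import numpy as np
import pytest

from lnmap.experiments import planted_recovery_experiment
from lnmap.synthetic import demo_grid
from lnmap.volumes import LesionMask, Volume, VolumeGrid


@pytest.fixture(scope="session")
def tiny_grid() -> VolumeGrid:
    """Fully-masked 4x4x4 grid at 2 mm isotropic."""
    shape = (4, 4, 4)
    return VolumeGrid(shape, np.diag([2.0, 2.0, 2.0, 1.0]),
                      np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def small_grid() -> VolumeGrid:
    return demo_grid((12, 14, 12))


def make_lesion(grid: VolumeGrid, flat_indices, case_id="case") -> LesionMask:
    vol = np.zeros(grid.shape, dtype=np.uint8)
    vol.ravel(order="C")[np.asarray(flat_indices)] = 1
    return LesionMask(case_id, Volume(grid, vol, kind="binary"))


@pytest.fixture(scope="session")
def planted_result():
    """Full-scale planted-network pipeline run shared by the acceptance
    checks: 100 subjects x 150 timepoints, coupling 0.8, noise sd 1,
    23 lesions, 5000 permutations."""
    return planted_recovery_experiment(seed=11, n_perm=5000)
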