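import numpy as np
import pytest

from cochleaquant.psf import make_psf
from cochleaquant.synth import (
    NoiseModel,
    VOLUMETRIC_VOXELS,
    plant_ground_truth,
    render_stack,
)


@pytest.fixture(scope="session")
def default_psf():
    return make_psf(0.2, 0.5, VOLUMETRIC_VOXELS)


@pytest.fixture(scope="session")
def small_field(default_psf):
    """A 5-cell rendered field with its ground truth (shared, read-only)."""
    gt = plant_ground_truth(n_cells=5, pairs_per_cell=16, seed=11)
    stack = render_stack(gt, default_psf, NoiseModel(), VOLUMETRIC_VOXELS, seed=11)
    return gt, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
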