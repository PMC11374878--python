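"""Shared fixtures: gradient tables and a reusable noiseless tube phantom."""

import numpy as np
import pytest

from tractometry.gradients import make_gradient_table
from tractometry.phantom import BundleGeometry, PhantomSpec, build_phantom
from tractometry.qball import fit_csa_odf

VOXEL = 1.25


@pytest.fixture(scope="session")
def gtab90():
    """Full acquisition scheme: 3 shells x 90 directions + 6 b0."""
    return make_gradient_table(90, [1000, 2000, 3000], 6, seed=0)


@pytest.fixture(scope="session")
def gtab30():
    """Reduced scheme for fast tests: 3 shells x 30 directions + 3 b0."""
    return make_gradient_table(30, [1000, 2000, 3000], 3, seed=0)


@pytest.fixture(scope="session")
def tube_phantom(gtab90):
    """Noiseless straight-tube phantom spanning the grid along x."""
    line = np.array([[0.0, 7 * VOXEL, 7 * VOXEL], [21 * VOXEL, 7 * VOXEL, 7 * VOXEL]])
    spec = PhantomSpec(
        (22, 14, 14), gtab90, [BundleGeometry("tube", line, 3.0)], voxel_size=VOXEL
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def tube_odf(tube_phantom, gtab90):
    return fit_csa_odf(tube_phantom.dwi, gtab90, mask=tube_phantom.wm_mask, sh_order=8)
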