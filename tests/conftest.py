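"""Shared fixtures: expensive simulator objects built once per session."""

import numpy as np
import pytest

from axilock.phantoms import SampleGrid, make_bead, make_neuron_slab
from axilock.psf import OpticalConfig, compute_psf
from axilock.simulate import scan_stack
from axilock.zernike import WavefrontCoeffs


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def grid():
    return SampleGrid()


@pytest.fixture(scope="session")
def psf0(optics):
    """Unaberrated two-photon PSF on the default grid."""
    return compute_psf(WavefrontCoeffs.zero(), optics)


@pytest.fixture(scope="session")
def bead_in_focus(grid):
    return make_bead(10.0, grid=grid)


@pytest.fixture(scope="session")
def slab(grid):
    """Default two-somata neuron slab (seed 0)."""
    return make_neuron_slab(seed=0, grid=grid)


@pytest.fixture(scope="session")
def slab_stack(slab, psf0):
    """Ideal z-stack of the slab over +-20 μm at the axial voxel step."""
    z = np.arange(-20.0, 20.0 + 1e-9, 0.8)
    return scan_stack(slab, psf0, z)
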