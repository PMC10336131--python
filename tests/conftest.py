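import numpy as np
import pytest

from edofscope import (BasisModel, CubicPhaseMask, OpticalModel, field_grid,
                       sensor_psf)


@pytest.fixture(scope="session")
def model_coarse():
    """Default optics with a coarse 75-um depth grid (5 planes) to keep
    simulation-heavy tests fast."""
    return OpticalModel(depth_step_um=75.0)


@pytest.fixture(scope="session")
def coded_mask(model_coarse):
    """The modulation strength selected by the design sweep on the default
    model."""
    return CubicPhaseMask(0.01, semi_diameter=model_coarse.pupil_semidiameter_mm)


@pytest.fixture(scope="session")
def field_uv9():
    return field_grid(3, 0.7)


@pytest.fixture(scope="session")
def coded_psfs9(model_coarse, coded_mask, field_uv9):
    """Nine coded sensor-pitch PSFs (33 px) at focus, one per field point."""
    return np.stack([sensor_psf(model_coarse, coded_mask, 0.0, tuple(f), size=33)
                     for f in field_uv9])


def make_exact_basis(psfs, field_uv):
    """Rank-M basis that reproduces the PSF matrix exactly: the bases are
    the PSFs themselves and W is the identity."""
    psfs = np.asarray(psfs, dtype=float)
    m = psfs.shape[0]
    shape = psfs.shape[1:]
    H = psfs.reshape(m, -1).T[None]          # (1, ab, M)
    W = np.eye(m)
    return BasisModel(H, W, np.asarray(field_uv, dtype=float), shape,
                      np.zeros(1))


@pytest.fixture(scope="session")
def exact_basis9(coded_psfs9, field_uv9):
    return make_exact_basis(coded_psfs9, field_uv9)
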