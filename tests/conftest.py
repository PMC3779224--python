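"""Shared fixtures: small noiseless phantoms and their reconstructions."""

import numpy as np
import pytest
from hypothesis import settings

from qconn.phantom import PhantomConfig, build_phantom, simulate_dwi

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from qconn.schemes import cartesian_hemisphere_scheme, uniform_sphere_scheme
from qconn.tessellation import icosphere


@pytest.fixture(scope="session")
def tess():
    return icosphere(3)


@pytest.fixture(scope="session")
def straight_truth():
    return build_phantom(PhantomConfig(geometry="straight", grid_shape=(16, 10, 10)))


@pytest.fixture(scope="session")
def crossing_truth():
    return build_phantom(
        PhantomConfig(geometry="crossing", angle=90.0, grid_shape=(20, 20, 8))
    )


@pytest.fixture(scope="session")
def dsi_scheme():
    return cartesian_hemisphere_scheme(5, 8000, name="DSIq5b8000")


@pytest.fixture(scope="session")
def qbi_scheme():
    return uniform_sphere_scheme(257, 3000, seed=0, name="QBI")


@pytest.fixture(scope="session")
def dti_scheme():
    return uniform_sphere_scheme(65, 1000, seed=0, name="DTI65")


@pytest.fixture(scope="session")
def straight_dsi(straight_truth, dsi_scheme):
    return simulate_dwi(straight_truth, dsi_scheme)


@pytest.fixture(scope="session")
def straight_qbi(straight_truth, qbi_scheme):
    return simulate_dwi(straight_truth, qbi_scheme)


@pytest.fixture(scope="session")
def crossing_dsi(crossing_truth, dsi_scheme):
    return simulate_dwi(crossing_truth, dsi_scheme)


@pytest.fixture(scope="session")
def crossing_qbi(crossing_truth, qbi_scheme):
    return simulate_dwi(crossing_truth, qbi_scheme)


def axial_error_deg(v, axis):
    v = np.asarray(v, float)
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    c = min(abs(float(v @ axis) / np.linalg.norm(v)), 1.0)
    return float(np.degrees(np.arccos(c)))
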