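"""Shared fixtures: small synthetic campaigns reused across test modules."""

import numpy as np
import pytest

from vesselvfm.geometry import (
    build_local_basis,
    build_sector_partition,
    solve_radial_scalar,
)
from vesselvfm.synthetic import TubeScenario, sample_measurements


def small_scenario(**kwargs) -> TubeScenario:
    """Desk-scale noiseless scenario for fast unit tests."""
    defaults = dict(
        noise_surface_um=0.0,
        noise_volume_um=0.0,
        mesh_ntheta=24,
        mesh_nz=8,
        mesh_nr=2,
        surface_grid=(36, 16),
        volume_shape=(32, 32, 40),
        seed=7,
    )
    defaults.update(kwargs)
    return TubeScenario(**defaults)


@pytest.fixture(scope="session")
def bundle():
    """Noiseless synthetic bundle (forward truth + emulated measurements)."""
    return sample_measurements(small_scenario())


@pytest.fixture(scope="session")
def mesh(bundle):
    return bundle.mesh


@pytest.fixture(scope="session")
def basis(mesh):
    return build_local_basis(mesh, solve_radial_scalar(mesh))


@pytest.fixture(scope="session")
def partition(mesh):
    return build_sector_partition(mesh, 2, 2)


@pytest.fixture(scope="session")
def fused(bundle):
    from vesselvfm.kinematics import build_fused_model

    return build_fused_model(bundle.surface, bundle.volume, bundle.radii)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
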