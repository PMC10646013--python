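import numpy as np
import pytest

from memdeform import (
    GridSpec2D,
    SyntheticBilayerSpec,
    generate_bilayer_trajectory,
    select_phosphorus,
)


@pytest.fixture(scope="session")
def flat_spec():
    """Noiseless flat bilayer: every particle sits exactly on its leaflet."""
    return SyntheticBilayerSpec(T0=40.0, D=0.0, noise_z=0.0, step_xy=1.0,
                                n_per_leaflet=64, n_frames=10, seed=11)


@pytest.fixture(scope="session")
def flat_traj(flat_spec):
    return generate_bilayer_trajectory(flat_spec)


@pytest.fixture(scope="session")
def well_spec():
    """Asymmetric thinning well, noiseless, for exact-surface checks."""
    return SyntheticBilayerSpec(T0=40.0, D=8.0, sigma_w=15.0, asym=1.0,
                                noise_z=0.0, step_xy=1.0, n_per_leaflet=128,
                                n_frames=5, seed=5)


@pytest.fixture
def p_mask(flat_traj):
    return select_phosphorus(flat_traj.topology)


@pytest.fixture
def grid(flat_spec):
    return GridSpec2D.from_box(np.diag([flat_spec.Lx, flat_spec.Ly, 60.0]))
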