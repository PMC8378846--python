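import numpy as np
import pytest

from polarfields.sectors import angular_edges_for_width, build_fine_grid
from polarfields.synth import CortexGenParams, generate_cortex


@pytest.fixture(scope="session")
def clean_cortex():
    """Noise-free asymmetric cortex at working resolution (h=0.3, v=0.2)."""
    params = CortexGenParams(h=0.3, v=0.2, mesh_step=1.0, angle_noise_sd=0.0,
                             ecc_noise_sd=0.0, ipsi_spill_prob=0.0, seed=42)
    return generate_cortex(params)


@pytest.fixture(scope="session")
def clean_grids(clean_cortex):
    edges = angular_edges_for_width(10)
    return {
        h: build_fine_grid(clean_cortex.bundles[h], clean_cortex.sectors[h], edges)
        for h in clean_cortex.bundles
    }


@pytest.fixture(scope="session")
def noisy_cortex():
    """Cortex with measurement noise and ipsilateral spill (defaults)."""
    params = CortexGenParams(mesh_step=1.0, seed=7)
    return generate_cortex(params)


@pytest.fixture(scope="session")
def isotropic_cortex():
    """No angular modulation: areas follow the radial magnification exactly."""
    params = CortexGenParams(h=0.0, v=0.0, mesh_step=1.0, angle_noise_sd=0.0,
                             ecc_noise_sd=0.0, ipsi_spill_prob=0.0, seed=1)
    return generate_cortex(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20210803)


def strip_mesh(n_quads: int, dx: float = 1.0, dy: float = 1.0):
    """Straight triangulated strip along x: 2 rows x (n_quads+1) columns."""
    xs = np.arange(n_quads + 1) * dx
    top = np.column_stack([xs, np.full_like(xs, dy), np.zeros_like(xs)])
    bot = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    coords = np.vstack([bot, top])  # bottom row ids 0..n, top ids n+1..2n+1
    nb = n_quads + 1
    faces = []
    for i in range(n_quads):
        faces.append([i, i + 1, nb + i])
        faces.append([i + 1, nb + i + 1, nb + i])
    return coords, np.asarray(faces, dtype=np.intp)
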