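import numpy as np
import pytest

import pclesr as P


@pytest.fixture(scope="session")
def small_lattice():
    """Desk-scale lattice: 120 fibres, FoV radius 28 on a 64x64 grid."""
    return P.generate_fibre_lattice(120, 28.0, (31.5, 31.5), jitter_frac=0.25, seed=11)


@pytest.fixture(scope="session")
def small_grid():
    return (64, 64)


@pytest.fixture(scope="session")
def phantom_pair(small_lattice, small_grid):
    """One phantom HR frame and its simulated LR partner."""
    hr = P.generate_phantom_hr(
        small_grid, small_lattice.fov_center, small_lattice.fov_radius, n_blobs=40, seed=5
    )
    lr = P.simulate_lr(hr, small_lattice, P.NoiseParams(seed=9))
    return P.ImagePair(lr=lr, hr=hr, pair_id="fix0", stratum="colon")


def brute_force_nearest(lattice, grid_shape):
    """Exhaustive per-pixel nearest-fibre assignment (lowest index on ties)."""
    mask = P.fov_mask(lattice, grid_shape)
    out = np.full(grid_shape, -1, dtype=int)
    pts = np.argwhere(mask).astype(float)
    d2 = ((pts[:, None, :] - lattice.positions[None, :, :]) ** 2).sum(axis=2)
    out[mask] = np.argmin(d2, axis=1)
    return out
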