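import numpy as np
import pytest

import memdeform as md
from memdeform.heightmap import GridSpec, HeightMap


@pytest.fixture(scope="session")
def default_system():
    """Full-featured small synthetic system: undulations, drift, protein,
    bump, noise and forces."""
    params = md.SyntheticParams(n_frames=10, seed=7)
    traj, topology, truth = md.generate(params)
    return params, traj, topology, truth


@pytest.fixture(scope="session")
def flat_system():
    """Degenerate flat bilayer: leaflets exactly at ±21 Å, no dynamics."""
    params = md.SyntheticParams(
        n_frames=4, seed=11, modes=(), noise_sigma=0.0,
        drift_upper_x=0.0, drift_lower_x=0.0, bump_amplitude=0.0,
        include_protein=False, with_forces=False,
    )
    traj, topology, truth = md.generate(params)
    return params, traj, topology, truth


def make_map(values, nx=4, ny=5, spacing=5.0, valid=None, time=0.0):
    """HeightMap from a flat list of heights laid row-major over a small grid."""
    grid = GridSpec(origin=(0.0, 0.0), spacing=spacing, nx=nx, ny=ny)
    heights = np.full((nx, ny), np.nan)
    mask = np.zeros((nx, ny), dtype=bool)
    values = np.asarray(values, dtype=float)
    flat_idx = np.arange(values.size)
    heights.ravel()[flat_idx] = values
    mask.ravel()[flat_idx] = True
    if valid is not None:
        mask = np.asarray(valid, dtype=bool).reshape(nx, ny)
        heights[~mask] = np.nan
    return HeightMap(grid=grid, heights=heights, valid=mask, time=time, leaflet="upper")


@pytest.fixture
def random_map():
    def _make(rng, n_cells=200, sigma=6.0, nx=16, ny=18):
        vals = rng.normal(20.0, sigma, size=n_cells)
        return make_map(vals, nx=nx, ny=ny)
    return _make
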