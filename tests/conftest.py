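import numpy as np
import pytest
from scipy.spatial.distance import cdist

from perilymph import simulate as sim
from perilymph.types import VesselMask


def brute_force_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Independent oracle: per-voxel min distance to any mask voxel.

    Direct minimum over all mask-voxel centre-to-centre distances with
    anisotropic spacing — O(N·M), usable only on small grids.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    src = np.argwhere(mask) * spacing
    axes = [np.arange(n) * s for n, s in zip(mask.shape, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, mask.ndim)
    return cdist(grid, src).min(axis=1).reshape(mask.shape)


def random_mask(rng: np.random.Generator, shape, p: float = 0.02) -> np.ndarray:
    """Sparse random boolean mask with at least one true voxel."""
    m = rng.random(shape) < p
    if not m.any():
        idx = tuple(rng.integers(0, n) for n in shape)
        m[idx] = True
    return m


@pytest.fixture
def straight_tube_2d() -> VesselMask:
    """Vertical tube at column 32, radius 3 µm, 64×64 px at 1 µm/px."""
    spec = sim.TubeSpec(control_points=[(0.0, 32.0), (63.0, 32.0)], radius_um=3.0)
    return sim.make_vessel_mask((64, 64), 1.0, geometry=spec)


@pytest.fixture
def tube_3d() -> VesselMask:
    """3-D tube along y, anisotropic spacing (1, 0.5, 0.5) µm."""
    spec = sim.TubeSpec(
        control_points=[(8.0, 0.0, 16.0), (8.0, 31.5, 16.0)], radius_um=3.0
    )
    return sim.make_vessel_mask((16, 64, 64), (1.0, 0.5, 0.5), geometry=spec)
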