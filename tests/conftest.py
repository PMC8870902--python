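import numpy as np
import pytest

from gelpen.preprocess import ValidityMask
from gelpen.stack_io import VoxelGeometry
from gelpen.surface import PenetrationMap


@pytest.fixture
def small_geometry() -> VoxelGeometry:
    """Quick 64x64x40 stack at 1x1x2 µm voxels."""
    return VoxelGeometry(nz=40, ny=64, nx=64, dz=2.0, dy=1.0, dx=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_penetration(values: np.ndarray, dx: float = 1.0, dy: float = 1.0,
                     valid: np.ndarray | None = None) -> PenetrationMap:
    """Wrap a plain 2-D array as a mode-zeroed penetration map for tests."""
    values = np.asarray(values, dtype=np.float64)
    if valid is None:
        valid = np.isfinite(values)
    geom = VoxelGeometry(nz=1, ny=values.shape[0], nx=values.shape[1], dz=1.0, dy=dy, dx=dx)
    return PenetrationMap(
        value_um=np.where(valid, values, np.nan),
        valid=ValidityMask(valid),
        geometry=geom,
        sigma_um=0.0,
        mode_shift_um=0.0,
        bin_um=1.0,
    )


def gaussian_pit_map(shape, pits, dx=1.0, dy=1.0):
    """Synthetic penetration surface: 0 background minus Gaussian pits.

    ``pits`` is a list of (x_um, y_um, depth_um, radius_um).
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x_um, y_um = xx * dx, yy * dy
    out = np.zeros(shape, dtype=np.float64)
    for (px, py, depth, radius) in pits:
        out -= depth * np.exp(-((x_um - px) ** 2 + (y_um - py) ** 2) / (2 * radius**2))
    return out
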