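import numpy as np
import pytest
from hypothesis import settings
from scipy import ndimage

from contourkit import BinaryMask, VoxelGrid

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def random_blob_mask(grid: VoxelGrid, rng: np.random.Generator, label: str = "s",
                     source: str = "", fill: float = 0.15) -> BinaryMask:
    """Smooth random blob occupying roughly ``fill`` of the grid (never empty)."""
    field = ndimage.gaussian_filter(rng.normal(size=grid.shape), sigma=2.0)
    occ = field > np.quantile(field, 1.0 - fill)
    if not occ.any():
        occ[tuple(s // 2 for s in grid.shape)] = True
    return BinaryMask(grid, occ, label=label, source=source)


def cube_mask(grid: VoxelGrid, lo, size, label: str = "s", source: str = "") -> BinaryMask:
    occ = np.zeros(grid.shape, dtype=bool)
    sl = tuple(slice(l, l + s) for l, s in zip(lo, size))
    occ[sl] = True
    return BinaryMask(grid, occ, label=label, source=source)


@pytest.fixture
def grid10():
    return VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))


@pytest.fixture
def grid_aniso():
    return VoxelGrid((12, 12, 6), (1.0, 1.0, 3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
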