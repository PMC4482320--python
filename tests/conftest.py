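import numpy as np
import pytest

import smncent as sc


@pytest.fixture(scope="session")
def small_mask() -> sc.BrainMask:
    """120-voxel connected mask on an 8x8x8 grid of 3 mm voxels."""
    return sc.make_toy_mask((8, 8, 8), 120, seed=7)


@pytest.fixture(scope="session")
def full_mask() -> sc.BrainMask:
    """All-true 4x4x4 mask (for smoothing/mean-preservation checks)."""
    grid = sc.ImageGrid.from_voxel_size((4, 4, 4), 3.0)
    return sc.BrainMask(grid, np.ones((4, 4, 4), dtype=bool))


def random_standardized(mask: sc.BrainMask, T: int, seed: int) -> sc.VoxelMatrix:
    """Row-standardised random matrix on a mask (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    vm = sc.VoxelMatrix(mask, rng.normal(size=(mask.n_voxels, T)))
    zvm, _ = sc.standardize_rows(vm)
    return zvm


def mask_of_size(n: int, seed: int = 0) -> sc.BrainMask:
    """Connected mask with exactly n voxels on a just-large-enough grid."""
    side = int(np.ceil(n ** (1 / 3))) + 2
    return sc.make_toy_mask((side, side, side), n, seed=seed)
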