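import numpy as np
import pytest

from intralobe.grids import GridSpec, ImageVolume, VOI


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), grid_id="g"):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(values.shape, tuple(spacing), tuple(origin), grid_id)
    return ImageVolume(values, grid)


def box_voi(volume, lo, hi, label="rough"):
    """All voxels with lo <= index <= hi (inclusive) on the volume's grid."""
    ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    return VOI(idx, volume.grid, label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
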