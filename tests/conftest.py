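import numpy as np
import pytest

from boldqc.core import Grid, Timeseries4D, VolumeMap


@pytest.fixture
def grid():
    return Grid.isotropic((6, 6, 4), 0.2)


@pytest.fixture
def full_mask(grid):
    return VolumeMap(np.ones(grid.shape, dtype=int), grid, kind="brain_mask")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_ts(full_mask, rng):
    n_vox = full_mask.count()
    return Timeseries4D(rng.standard_normal((n_vox, 50)), full_mask, tr=1.2)


def make_ts(values, mask, tr=1.2):
    return Timeseries4D(np.asarray(values, dtype=float), mask, tr=tr)
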