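import numpy as np
import pytest
from hypothesis import settings

import shallowcn as sc

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_grid():
    """One 500 kb chromosome of ten 50 kb bins."""
    return sc.simulate_grid(1, 500_000, 50_000, gc_profile_seed=0)


@pytest.fixture
def two_chrom_grid():
    return sc.simulate_grid(2, 525_000, 50_000, gc_profile_seed=1)


@pytest.fixture
def diploid_truth(small_grid):
    return sc.simulate_truth(small_grid, 0, (50_000, 50_000), seed=0)


def make_track(grid, values, sample_id="t"):
    """RatioTrack from raw values (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    reason = np.full(grid.n_bins, None, dtype=object)
    reason[~np.isfinite(values)] = "user"
    return sc.RatioTrack(grid, values, reason, sample_id=sample_id)


def uniform_profile(grid, mean, sample_id="p", gain_thr=0.15, loss_thr=-0.15):
    """Single-segment-per-chromosome profile with a constant mean."""
    segs = [
        sc.Segment(chrom=name, start=0, end=length,
                   n_bins=(length + grid.bin_size - 1) // grid.bin_size, mean=mean)
        for name, length in grid.chromosomes
    ]
    return sc.call_segments(segs, gain_thr=gain_thr, loss_thr=loss_thr,
                            sample_id=sample_id)
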