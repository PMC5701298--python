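import numpy as np
import pytest

from scith.grid import BinGrid
from scith.profiles import CopyNumberProfile
from scith.simulate import CNEvent, MutationSpec, SimConfig


@pytest.fixture
def small_grid():
    """Two chromosomes, 10 Mb each, 500 kb bins -> 40 bins."""
    return BinGrid.tile([("chr1", 10_000_000), ("chr2", 10_000_000)], 500_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_profile(grid, ratio, sample_id="cell", mask=None):
    ratio = np.asarray(ratio, dtype=float)
    with np.errstate(divide="ignore"):
        log2r = np.log2(ratio)
    if mask is None:
        mask = np.isfinite(log2r)
    return CopyNumberProfile(sample_id, grid, ratio, log2r, mask)


@pytest.fixture
def two_clone_config():
    """One region, two tumor clones differing by a 5 Mb CN-4 gain."""
    return SimConfig(
        genome_spec=[("chr1", 30_000_000), ("chr2", 30_000_000)],
        clone_tree={"major": None, "minor": "major"},
        event_list=[
            CNEvent("major", "chr1", 0, 10_000_000, 3),
            CNEvent("minor", "chr2", 5_000_000, 10_000_000, 4),
        ],
        clone_fractions_per_region={"A": {"major": 0.7, "minor": 0.3}},
        depth_mean=100.0,
        target_mapd=0.20,
        n_cells_per_region=35,
        mutation_spec=[
            MutationSpec("m0", "chr1", 100, "C", "T", ("major", "minor")),
            MutationSpec("m1", "chr1", 500, "G", "A", ("minor",)),
        ],
        seed=7,
    )
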