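import numpy as np
import pytest

from neurocrit.raster import EventRaster
from neurocrit.simulate import BranchingParams, simulate_branching_raster


@pytest.fixture(scope="session")
def critical_raster():
    """Moderate-size critical branching raster shared across test modules."""
    return simulate_branching_raster(
        BranchingParams(n_channels=64, n_bins=100_000, branching_ratio=1.0,
                        drive_rate=0.01, seed=101)
    )


@pytest.fixture(scope="session")
def subcritical_raster():
    return simulate_branching_raster(
        BranchingParams(n_channels=64, n_bins=100_000, branching_ratio=0.2,
                        drive_rate=0.01, seed=101)
    )


@pytest.fixture()
def toy_raster():
    """Events at (ch0,t1),(ch1,t1),(ch2,t2),(ch0,t5) on a 3x8 grid."""
    return EventRaster(
        np.array([0, 1, 2, 0]), np.array([1, 1, 2, 5]), n_channels=3, n_bins=8
    )
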