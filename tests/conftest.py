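import numpy as np
import pytest

import blocksdm as b
from blocksdm.grid_io import Grid, GridHeader


@pytest.fixture(scope="session")
def world():
    """Default synthetic study system (60x60 cells, 24 covariates)."""
    return b.make_world(seed=0)


@pytest.fixture(scope="session")
def training(world):
    """A small assembled training set on the session world."""
    pts = b.sample_presences(world.truth, world.bias, 400, seed=100)
    occ, feat = b.assemble_training_set(
        pts, b.PseudoAbsenceConfig(seed=300), world.stack
    )
    return occ, feat


@pytest.fixture
def small_header():
    return GridHeader(ncols=4, nrows=3, xllcorner=10.0, yllcorner=50.0, cellsize=0.5)


@pytest.fixture
def ramp_grid(small_header):
    values = np.arange(12, dtype=float).reshape(3, 4)
    return Grid(small_header, values)
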