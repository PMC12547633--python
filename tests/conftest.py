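import numpy as np
import pytest

from cumex.grid import LAND, MIXED, SEA, GridDef


@pytest.fixture
def sea_grid():
    """4x4 all-sea grid in the Southern Hemisphere."""
    return GridDef.regular(-40.0, 10.0, 4, 4, surface_class=SEA)


@pytest.fixture
def coastal_grid():
    """5x6 grid: two land columns, a mixed coastal column, sea to the east."""
    cls = np.full((5, 6), SEA, dtype=object)
    cls[:, :2] = LAND
    cls[:, 2] = MIXED
    return GridDef.regular(-40.0, 0.0, 5, 6, surface_class=cls)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
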