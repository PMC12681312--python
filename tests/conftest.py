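import numpy as np
import pytest

from epinav.geometry import Grid3D
from epinav.phantom import (
    PhantomSpec,
    make_b1_transmit_maps,
    make_coil_sensitivities,
    make_phantom,
)


@pytest.fixture(scope="session")
def small_grid():
    """Tiny grid for operator-level tests."""
    return Grid3D.centered((16, 16, 16), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def phantom_grid():
    """Mid-size grid for phantom-based tests (divisible by the CAIPI lattices)."""
    return Grid3D.centered((24, 16, 16), (8.0, 11.0, 9.0))


@pytest.fixture(scope="session")
def phantom_and_mask(phantom_grid):
    return make_phantom(PhantomSpec(phantom_grid, 3, seed=7))


@pytest.fixture(scope="session")
def coils8(phantom_grid):
    return make_coil_sensitivities(phantom_grid, 8, seed=3).maps


@pytest.fixture(scope="session")
def b1_16ch():
    grid = Grid3D.centered((20, 18, 16), (8.0, 8.0, 8.0))
    return grid, make_b1_transmit_maps(grid, 16, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
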