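import numpy as np
import pytest

import quadgait as qg


@pytest.fixture(scope="session")
def species_table():
    return qg.load_species_table()


@pytest.fixture(scope="session")
def phase_grid():
    """Half-percent phase grid with the symmetry phases on nodes."""
    return np.arange(0.0, 100.0, 0.5)


@pytest.fixture(scope="session")
def base_surface(phase_grid):
    """Base-variant cost surface at three representative duty factors."""
    return qg.compute_cost_surface("base", [0.60, 0.65, 0.85], phase_grid)
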