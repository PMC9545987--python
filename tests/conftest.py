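import numpy as np
import pytest

from spectremri.simulate import (
    default_phantom,
    default_protocol,
    simulate_coil_sensitivities,
    simulate_dwi_series,
)


@pytest.fixture(scope="session")
def small_setup():
    """Small simulated acquisition shared by reconstruction tests:
    64x64x2 grid, 8 coils, 11 volumes (2 b=0 + 3 shells x 3 directions)."""
    grid = (64, 64, 2)
    phantom = default_phantom(grid)
    protocol = default_protocol(n_dirs=3, n_b0=2)
    images = simulate_dwi_series(phantom, protocol)
    coils = simulate_coil_sensitivities(8, grid, seed=1)
    return {
        "grid": grid,
        "phantom": phantom,
        "protocol": protocol,
        "images": images,
        "coils": coils,
    }
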