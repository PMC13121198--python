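import numpy as np
import pytest

from finblock.volume_conductor import (
    ConductivityProfile,
    ElectrodeSpec,
    GridSpec,
    Layer,
    solve_bipolar_field,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """A compact grid for fast field tests (not enclosing the electrodes)."""
    return GridSpec.from_bounds((-200, -200, -200), (200, 200, 200), 40.0)


@pytest.fixture(scope="session")
def homogeneous_setup():
    """Disc pair in a uniform medium with the box walls pushed far out."""
    sigma = 0.6
    profile = ConductivityProfile((Layer("medium", 7200.0, sigma),))
    grid = GridSpec.from_bounds((-3600, -3600, -3600), (3600, 3600, 3600),
                                120.0)
    src = ElectrodeSpec((0, 0, -600), diameter_um=200, role="current_source")
    gnd = ElectrodeSpec((0, 0, 600), diameter_um=200, role="ground")
    pm = solve_bipolar_field(profile, src, gnd, grid, end_faces="insulate")
    return sigma, pm, src, gnd


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
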