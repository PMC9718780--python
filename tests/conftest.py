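import numpy as np
import pytest

from orientnull import build_phase_diagram

DIAGRAM_SEED = 42


@pytest.fixture(scope="session")
def vm21():
    """Von Mises phase diagram for the diver-followed design (N_obs = 21)."""
    return build_phase_diagram("von_mises", 21, n_rep=1000, seed=DIAGRAM_SEED)


@pytest.fixture(scope="session")
def wc21():
    """Wrapped Cauchy diagram at N_obs = 21 (reduced rho grid for speed)."""
    grid = np.linspace(0.0, 0.999, 100)
    return build_phase_diagram("wrapped_cauchy", 21, n_rep=300, seed=DIAGRAM_SEED, conc_grid=grid)


@pytest.fixture(scope="session")
def vm90_coarse():
    """Von Mises diagram at N_obs = 90 on a thinned concentration grid."""
    grid = np.arange(0, 400, 8, dtype=float)
    return build_phase_diagram("von_mises", 90, n_rep=300, seed=DIAGRAM_SEED, conc_grid=grid)
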