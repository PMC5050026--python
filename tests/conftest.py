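import numpy as np
import pytest

from confex.systems import DoubleWell1D, make_two_state_beads


@pytest.fixture(scope="session")
def double_well():
    """Standard asymmetric two-state model (barrier 7 kBT, gap 1.5 kBT)."""
    return DoubleWell1D(barrier=7.0, delta_G_true=1.5)


@pytest.fixture(scope="session")
def beads():
    """Seeded two-state bead model with its reference conformations."""
    model, A, B = make_two_state_beads(
        n_beads=5, displacement=2.0, delta_G_true=1.5, barrier=5.0, seed=42
    )
    return model, A, B


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
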