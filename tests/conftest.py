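import numpy as np
import pytest

from ceaphys.simulate import SimConfig, simulate_calcium_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across tests (20 no-effect neurons)."""
    config = SimConfig(
        seed=3, n_neurons=20, frac_inhibited=0.0, frac_excited=0.0, amp_sd=0.0
    )
    return simulate_calcium_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
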