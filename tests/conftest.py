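import numpy as np
import pytest

from popdyn import synthetic


@pytest.fixture(scope="session")
def susceptible_session():
    """One susceptible-profile session, shared across tests (read-only)."""
    return synthetic.simulate_session(
        synthetic.SUSCEPTIBLE, n_trials=120, n_neurons=16, seed=101)


@pytest.fixture(scope="session")
def control_session():
    return synthetic.simulate_session(
        synthetic.CONTROL, n_trials=120, n_neurons=16, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
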