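import numpy as np
import pytest
from hypothesis import settings

from cellscale import growth, nucleus, synth

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def growth_params():
    return growth.default_growth_params()


@pytest.fixture(scope="session")
def growth_traj(growth_params):
    """One full trajectory crossing all three regimes."""
    return growth.simulate_growth(growth_params, np.linspace(0.0, 10.0, 201))


@pytest.fixture(scope="session")
def nested_params():
    return nucleus.default_nested_params()


@pytest.fixture(scope="session")
def true_fit_params():
    return synth.default_true_params()
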