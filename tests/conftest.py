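import numpy as np
import pytest

from ernet import build_reference_model, load_default_parameters
from ernet.network import equilibrate, run_scenario_panel, run_treated_panel


@pytest.fixture(scope="session")
def model():
    return build_reference_model()


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def baseline_state(model, params):
    return equilibrate(model, params)


@pytest.fixture(scope="session")
def panel(model, params):
    """Five-preset scenario panel, shared across tests (simulation is costly)."""
    return run_scenario_panel(model, params)


@pytest.fixture(scope="session")
def treated_panel(model, params):
    return run_treated_panel(model, params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
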