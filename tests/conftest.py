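import numpy as np
import pytest

from dynpet.core import default_schedule
from dynpet.input_function import InputFunctionModel
from dynpet.kinetics import KineticParams


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def b_params():
    """Group-B median kinetic parameters."""
    return KineticParams(K1=0.3506, k2=0.5216, k3=0.1177, k4=0.1005, vb=0.0903)


@pytest.fixture(scope="session")
def r_params():
    """Group-R median kinetic parameters."""
    return KineticParams(K1=0.2728, k2=0.5721, k3=0.1180, k4=0.0442, vb=0.0574)


@pytest.fixture(scope="session")
def input_model():
    """A three-exponential blood curve with a fast washout term."""
    return InputFunctionModel(
        terms=((1.1e6, 4.0), (3.6e5, 0.35), (1.8e5, 0.02)), delay_t0=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
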