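import numpy as np
import pytest

from ecikin import reference as ref
from ecikin.synthetic import KineticScenario


@pytest.fixture(scope="session")
def days_0_90():
    return np.arange(91.0)


@pytest.fixture(params=list(ref.TOAST_LEVELS))
def toast_level(request):
    return request.param


@pytest.fixture
def noiseless_scenario(toast_level):
    """Reference kinetic scenario with noise and late ramp switched off."""
    return KineticScenario.from_toast_level(toast_level, noise_sd=0.0, late_slope=0.0)
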