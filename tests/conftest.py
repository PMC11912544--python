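import pytest

from autoreg.model import (CMH2O_PA, MMHG_PA, ExperimentProtocol, StepEvent,
                           nominal_parameters)
from autoreg.synthetic import make_suite


@pytest.fixture(scope="session")
def params():
    """Nominal vessel at the 30-um / 60-cmH2O / 5-mmHg in-situ reference."""
    return nominal_parameters()


@pytest.fixture(scope="session")
def baseline_protocol():
    """Constant-input protocol at the cannulated baseline (35 cmH2O, 5 mmHg)."""
    return ExperimentProtocol(PI_base=35 * CMH2O_PA, dP_base=5 * MMHG_PA,
                              duration=300.0)


@pytest.fixture(scope="session")
def dp_step_protocol():
    """Pressure-gradient up-step (endothelial dilation, shear non-decreasing)."""
    return ExperimentProtocol(
        PI_base=35 * CMH2O_PA, dP_base=5 * MMHG_PA, duration=300.0,
        events=(StepEvent(60.0, "dP", 5 * MMHG_PA + 8 * CMH2O_PA),))


@pytest.fixture(scope="session")
def suite():
    """Shared-truth synthetic suite with the default 0.5-um noise."""
    return make_suite(seed=7)


@pytest.fixture(scope="session")
def noiseless_suite():
    return make_suite(noise_sd=0.0, seed=7)
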