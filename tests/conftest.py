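import numpy as np
import pytest

from antcut import fit_calibration
from antcut.simulate import DEFAULT_SENSOR, QuadraticSensor, gen_calibration_table


@pytest.fixture(scope="session")
def default_calibration():
    """Calibration model fitted to a noiseless table from the default
    quadratic sensor; exact within the 10-245 mN range."""
    table = gen_calibration_table(DEFAULT_SENSOR)
    return fit_calibration(table["force_N"].to_numpy(), table["reading"].to_numpy())


@pytest.fixture(scope="session")
def identity_sensor():
    """Sensor whose raw reading equals the force in newtons."""
    return QuadraticSensor(c0=0.0, c1=1.0, c2=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
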