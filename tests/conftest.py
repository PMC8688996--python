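import warnings

import numpy as np
import pytest

from swimphase import orientation as ori
from swimphase.synthetic import LapScenario, simulate_lap


@pytest.fixture(scope="session")
def default_lap():
    """One front-crawl lap at the default noise level."""
    return simulate_lap(LapScenario(seed=11))


@pytest.fixture(scope="session")
def quiet_lap():
    """Noise-free front-crawl lap."""
    return simulate_lap(LapScenario(acc_noise=0.0, gyr_noise=0.0, seed=12))


@pytest.fixture(scope="session")
def prepared_lap(default_lap):
    """Calibrated, fused and globally rotated signals for ``default_lap``."""
    lap = default_lap
    rec_a = ori.apply_calibration(lap.imu_sensor, lap.calibration)
    q0 = ori.estimate_initial_orientation(rec_a.slice(0.5, 5.5))
    trace = ori.fuse_orientation(rec_a, q0)
    rec_g = ori.rotate_to_global(rec_a, trace)
    return lap, rec_a, trace, rec_g


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
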