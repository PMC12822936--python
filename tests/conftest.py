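"""Shared fixtures: the hand-written cohort and one calibrated noise map.

Noise calibration is the only expensive step, so it is session-scoped and
shared by the simulator and acceptance tests.
"""

import pytest

from dfuvalid.simulate import SimulationConfig, calibrate_noise, fixture_small


@pytest.fixture(scope="session")
def small_cohort():
    return fixture_small()


@pytest.fixture(scope="session")
def calibration_config():
    return SimulationConfig(seed=5)


@pytest.fixture(scope="session")
def calibrated_noise(calibration_config):
    return calibrate_noise(calibration_config)
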