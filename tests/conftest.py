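from pathlib import Path

import pytest

import ringqa as rq

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def geom():
    return rq.default_geometry()


@pytest.fixture(scope="session")
def plan():
    return rq.default_plan()


@pytest.fixture(scope="session")
def baseline_frame(plan, geom):
    """Noise-free delivery with all parameters nominal."""
    return rq.simulate_measurement(plan, geom, rq.DeliveryParams())


@pytest.fixture(scope="session")
def clean_suite(plan, geom):
    """The 43-delivery intentional-shift suite, noise-free."""
    return rq.make_validation_suite(plan, geom, noise_sd=0.0)


@pytest.fixture(scope="session")
def cal(plan, geom, clean_suite):
    """Calibration fitted on the noise-free suite."""
    return rq.calibrate(plan, geom, clean_suite)
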