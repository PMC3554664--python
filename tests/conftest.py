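import numpy as np
import pytest

from azipkpd.config import default_params
from azipkpd.synthetic_data import DEFAULT_LANDMARKS, calibrate_cascade


@pytest.fixture(scope="session")
def params():
    """Published PK/PD parameter tables (slopes uncalibrated)."""
    return default_params()


@pytest.fixture(scope="session")
def calibration(params):
    """Best-effort landmark calibration (shared across the session: the
    nested 1-D searches take a few seconds)."""
    return calibrate_cascade(DEFAULT_LANDMARKS, params, strict=False)


@pytest.fixture(scope="session")
def truth(calibration):
    """Calibrated parameter set used as generator ground truth."""
    return calibration.paramset


@pytest.fixture(scope="session")
def azi_normal(params):
    return params.azi_pk["normal"]


@pytest.fixture(scope="session")
def lps_normal(params):
    return params.lps_pk["normal"]
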