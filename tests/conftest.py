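import numpy as np
import pytest

from rhozeff.hu_calibration import CalibrationCurve
from rhozeff.icru import ICRU_TISSUES, default_zeff_definition
from rhozeff.synthetic import make_default_curve
from rhozeff.tissue_db import build_database


@pytest.fixture(scope="session")
def zeff_def():
    return default_zeff_definition()


@pytest.fixture(scope="session")
def icru_table():
    return ICRU_TISSUES


@pytest.fixture(scope="session")
def default_curve():
    return make_default_curve()


@pytest.fixture(scope="session")
def toy_curve():
    """Linear calibration HU = -773 + 100 x expressed as a degenerate cubic."""
    return CalibrationCurve(coeffs=(-773.0, 100.0, 0.0, 0.0), domain=(2.0, 27.0))


@pytest.fixture(scope="session")
def default_db():
    """The full 125-tissue database (built once per session)."""
    return build_database()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
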