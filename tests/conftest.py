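import numpy as np
import pytest
from hypothesis import settings

from dmpk.quantitation import CalibrationStandard

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

TRUE_SLOPE = 0.023
TRUE_INTERCEPT = 0.006
NINE_LEVELS = (0.2, 0.5, 1.0, 2.0, 5.0, 20.0, 50.0, 200.0, 500.0)


def make_standards(levels=NINE_LEVELS, slope=TRUE_SLOPE, intercept=TRUE_INTERCEPT, noise=None):
    """Standards whose responses lie on (or around) a known line."""
    standards = []
    for i, x in enumerate(levels):
        response = slope * x + intercept
        if noise is not None:
            response *= noise[i]
        standards.append(CalibrationStandard(x, analyte_area=response * 1000.0, is_area=1000.0))
    return standards


@pytest.fixture
def noiseless_standards():
    return make_standards()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
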