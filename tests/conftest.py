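import numpy as np
import pytest

import ureafit as uf


@pytest.fixture(scope="session")
def measured():
    """The 9 measured L9 calibration runs."""
    return uf.load_measured_runs()


@pytest.fixture(scope="session")
def predicted():
    """The 18 externally predicted factorial runs (ids 10-27)."""
    return uf.load_predicted_runs()


@pytest.fixture(scope="session")
def reference():
    return uf.REFERENCE_COEFFS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
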