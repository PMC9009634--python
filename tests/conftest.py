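import numpy as np
import pytest

from dtpln import SampleData, rainfall_fixture, fit


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def rainfall() -> SampleData:
    return rainfall_fixture()


@pytest.fixture(scope="session")
def rainfall_est(rainfall):
    return fit(rainfall)
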