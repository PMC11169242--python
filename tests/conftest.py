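import numpy as np
import pytest

from naloxsim import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def engine_factory():
    """Fresh canonical engine per call (deterministic batch runs)."""

    def make(dt=0.1, **kw):
        return fixtures.make_engine(dt=dt, **kw)

    return make


@pytest.fixture
def fentanyl():
    return fixtures.default_fentanyl()


@pytest.fixture
def naloxone():
    return fixtures.default_naloxone()


@pytest.fixture
def patient():
    return fixtures.default_patient()
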