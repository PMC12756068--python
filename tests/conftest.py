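import numpy as np
import pytest

from frocdwi import AcquisitionProtocol
from frocdwi.synthetic import DEFAULT_B_VALUES, default_protocol


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    """The default 8-b breast protocol (delta = 19.3 ms, Delta = 40 ms)."""
    return default_protocol()


@pytest.fixture(scope="session")
def b_values() -> np.ndarray:
    return np.asarray(DEFAULT_B_VALUES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)
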