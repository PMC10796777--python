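import numpy as np
import pytest

from laflow.anatomy import build_idealized_la
from laflow.config import subject_config


@pytest.fixture(scope="session")
def subject1_config():
    return subject_config(1)


@pytest.fixture(scope="session")
def subject1_surface(subject1_config):
    return build_idealized_la(subject1_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
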