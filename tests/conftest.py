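import numpy as np
import pytest

from netmark import MutationModel
from netmark.fixtures import load_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20180110)


@pytest.fixture
def model():
    return MutationModel(1.0, 1.0)


@pytest.fixture
def net_1retic():
    return load_fixture("model_1retic")


@pytest.fixture
def net_2retic():
    return load_fixture("model_2retic")


@pytest.fixture
def net_4taxon():
    return load_fixture("model_4taxon")
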