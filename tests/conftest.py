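import numpy as np
import pytest

from speechpriors.filterbank import make_filterbank
from speechpriors.vocoder import VocoderConfig, synth_speechlike


@pytest.fixture(scope="session")
def fb8():
    return make_filterbank(8)


@pytest.fixture(scope="session")
def fb16():
    return make_filterbank(16)


@pytest.fixture(scope="session")
def cfg8(fb8):
    return VocoderConfig(filterbank=fb8)


@pytest.fixture(scope="session")
def sentence_pair():
    """Two distinct short synthetic sentences at 22.05 kHz."""
    return synth_speechlike(1.5, seed=101), synth_speechlike(1.5, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
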