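import numpy as np
import pytest

from phasekit import seqcharge


@pytest.fixture(scope="session")
def npm1():
    return seqcharge.load_npm1()


@pytest.fixture(scope="session")
def npm1_annotation():
    return seqcharge.load_npm1_tracts()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
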