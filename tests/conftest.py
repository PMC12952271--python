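import numpy as np
import pytest

from cdrgen.seqspace import AB14_CDR_WT, SearchConstraints, WildType


@pytest.fixture
def wt():
    return WildType(AB14_CDR_WT)


@pytest.fixture
def toy_wt():
    # short wild type over the full alphabet for fast enumeration tests
    return WildType("ACD")


@pytest.fixture
def constraints():
    return SearchConstraints(d_lim=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
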