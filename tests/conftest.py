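import numpy as np
import pytest

from autocat.examples import (
    cbb_lumped_network,
    glycolysis_atp_network,
    glyoxylate_network,
    pts_network,
)


@pytest.fixture
def glyoxylate():
    return glyoxylate_network()


@pytest.fixture
def pts():
    return pts_network()


@pytest.fixture
def glycolysis_atp():
    return glycolysis_atp_network()


@pytest.fixture
def cbb():
    return cbb_lumped_network()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
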