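import numpy as np
import pytest
from hypothesis import settings

from tunnelseq.calibration import default_table
from tunnelseq.motifs import p53_motif

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def p53():
    return p53_motif()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
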