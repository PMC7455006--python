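import numpy as np
import pytest
from hypothesis import settings

from rnaworld.sequences import REPLICASE_MOTIF, ReplicaseMotif

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def motif():
    return ReplicaseMotif()


@pytest.fixture
def motif_seq():
    return REPLICASE_MOTIF
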