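import numpy as np
import pytest
from hypothesis import settings

from nadcapseq import simdata

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

# compact transcripts keep amplicons well within merged-pair reach
SMALL_LENGTHS = {"utr5": (20, 60), "cds": (300, 500), "utr3": (50, 150)}


@pytest.fixture(scope="session")
def small_transcriptome():
    return simdata.generate_transcriptome(5, length_params=SMALL_LENGTHS, seed=7)


@pytest.fixture(scope="session")
def one_model(small_transcriptome):
    return small_transcriptome[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
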