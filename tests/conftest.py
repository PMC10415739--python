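import numpy as np
import pytest

import tmsdrop as td
from tmsdrop.pool_thermo import generate_random_pool, pool_ddGs

# a fixed 25-mer invader used across thermodynamics tests (the droplet
# experiments' invader sequence is not public; any fixed 25-mer exercises
# the same model)
INVADER_25 = "GTCAGTTGAGGATCCACGTATGCTT"


@pytest.fixture(scope="session")
def invader25() -> td.DNAStrand:
    return td.DNAStrand("invader", INVADER_25)


@pytest.fixture(scope="session")
def pool_10k(invader25):
    """10^4-strand N25 surrogate pool and its ddG spectrum."""
    strands = generate_random_pool(10_000, 25, seed=3)
    return strands, pool_ddGs(invader25, strands)


@pytest.fixture(scope="session")
def acq() -> td.AcquisitionConfig:
    return td.AcquisitionConfig()


@pytest.fixture()
def clean_emulsion():
    cfg = td.EmulsionConfig(n_droplets=50, radius_cv=0.0, mixing_mode="fixed")
    return td.generate_emulsion(cfg, seed=1)


@pytest.fixture()
def noiseless_traces(clean_emulsion, acq):
    return td.simulate_trace_set(
        clean_emulsion,
        td.RateParameters(td.K_CLEAN, "clean"),
        acq,
        td.NoiseModel(0.0, 0.0),
        seed=1,
    )
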