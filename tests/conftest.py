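import numpy as np
import pytest

from svmrd import SimConfig
from svmrd.simulate import make_genome
from svmrd.sv_targets import GenomeSequence


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def unique_genome(sim_config) -> GenomeSequence:
    """A small random genome with no duplicated 15-mer on either strand."""
    return make_genome(sim_config, n_contigs=2, contig_len=20_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
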