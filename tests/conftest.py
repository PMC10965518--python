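import numpy as np
import pytest

from svsnv.genome import GenomeDef
from svsnv.synthetic_data import simulate_genome, synthetic_signature_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_genome_and_seq():
    """Two small chromosomes with reproducible random sequence."""
    return simulate_genome({"chrA": 10_000, "chrB": 6_000}, seed=11)


@pytest.fixture
def toy_genome(toy_genome_and_seq):
    return toy_genome_and_seq[0]


@pytest.fixture
def toy_sequences(toy_genome_and_seq):
    return toy_genome_and_seq[1]


@pytest.fixture(scope="session")
def sig_matrix():
    """synGC + synAT + one peaked random column (synNEAR)."""
    return synthetic_signature_matrix(seed=5, n_random=1)


@pytest.fixture
def mb_genome():
    """A 1 Mb single-chromosome genome for brute-force interval oracles."""
    return GenomeDef.from_lengths({"chr1": 1_000_000})
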