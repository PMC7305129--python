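import numpy as np
import pytest

from nitroprof import profiling as prof
from nitroprof import synthetic as syn


@pytest.fixture(scope="session")
def profiles():
    return prof.build_default_profiles()


@pytest.fixture(scope="session")
def small_sample():
    """A 4,000-read simulated sample shared by profiling-level tests."""
    community = syn.default_community(seed=11, n_reads=4000)
    genomes = syn.build_community_genomes(community)
    reads, truth = syn.simulate_reads(community, genomes)
    refdb = syn.build_reference_db(genomes)
    return community, genomes, reads, truth, refdb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_dna(n, seed):
    r = np.random.default_rng(seed)
    return "".join(r.choice(list("ACGT"), size=n))


def substitute(seq, n_subs, seed):
    """Substitute exactly n_subs positions to a different base."""
    r = np.random.default_rng(seed)
    positions = r.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in positions:
        chars[p] = "ACGT".replace(chars[p], "")[r.integers(3)]
    return "".join(chars)
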