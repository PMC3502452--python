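import numpy as np
import pytest

from refree.formats_io import SequenceRecord
from refree.simulation import SimulationConfig, make_genome, simulate_reads


@pytest.fixture
def rng():
    return np.random.default_rng(20120)


@pytest.fixture
def small_genome():
    """A 10 kb quadripartite genome (5k LSC + 1.4k SSC + 2 x 1.8k IR)."""
    return make_genome(5000, 1400, 1800, seed=7)


@pytest.fixture
def small_reads(small_genome):
    """Error-free 51 bp paired reads at 20x from the small genome."""
    return simulate_reads(
        small_genome,
        SimulationConfig(read_len=51, coverage=20.0, error_rate=0.0, paired=True,
                         seed=11),
    )


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def record_factory():
    def make(seq: str, rid: str = "r", qual=None) -> SequenceRecord:
        return SequenceRecord(id=rid, sequence=seq, quality=qual)

    return make
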