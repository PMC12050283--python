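import pytest

from eccforge.mapper import GenomeIndex
from eccforge.sim import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def genome():
    """Shared toy genome: 2 x 100 kb, default annotation density."""
    return generate_genome(GenomeSpec(seed=11))


@pytest.fixture(scope="session")
def genome_index(genome):
    return GenomeIndex(genome.seqs, k=15)
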