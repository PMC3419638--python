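import numpy as np
import pytest

from bespipe.io_formats import SeqRecord
from bespipe.synthetic import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """Five 200 kb chromosomes of random sequence (1 Mb total)."""
    g = np.random.default_rng(101)
    return {f"chr{i + 1}": random_sequence(g, 200_000, 0.44) for i in range(5)}


@pytest.fixture(scope="session")
def small_index(small_genome):
    from bespipe.mapping import SeedIndex
    return SeedIndex.build(small_genome, k=15)


def make_read(read_id: str, genome: dict, chrom: str, start: int, length: int,
              strand: str = "+") -> SeqRecord:
    from bespipe.io_formats import revcomp
    seq = genome[chrom][start:start + length]
    return SeqRecord(read_id, seq if strand == "+" else revcomp(seq))
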