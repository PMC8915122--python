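import numpy as np
import pytest

from srnakit.alignments_io import Alignment
from srnakit import synthetic_data as sd


@pytest.fixture
def genome():
    """Fresh 100 kb random genome (simulators mutate it in place)."""
    return sd.make_genome(1, 100_000, gc=0.4, seed=7)


def random_reads(rng, n, span=5000, contig="ctg1", offset=1000,
                 len_range=(15, 32), with_seq=False, genome=None):
    """Uniform random alignments for oracle-equivalence checks."""
    reads = []
    for _ in range(n):
        ln = int(rng.integers(len_range[0], len_range[1] + 1))
        start = offset + int(rng.integers(span - ln))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = None
        if genome is not None:
            seq = genome.read_sequence(Alignment(contig, start, start + ln, strand))
        elif with_seq:
            seq = "".join(rng.choice(list("ACGT"), size=ln))
        reads.append(Alignment(contig, start, start + ln, strand, seq,
                               n_hits=int(rng.integers(1, 4)),
                               count=int(rng.integers(1, 4))))
    return reads


@pytest.fixture
def rng():
    return np.random.default_rng(42)
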