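import numpy as np
import pytest

from diplosplice import GenomeSequence, IntronRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_genome():
    """Two small contigs with a known plus-strand intron layout."""
    # contig c1: exon(10) + intron GTAAGT...CTCAG-style + exon(10)
    intron = "GTAAGT" + "ACGTACGTACGTACGTACGTACGTAC" + "CCTCAG"  # 38 nt, GT..AG
    c1 = "ACGTACGTAC" + intron + "TTGCATTGCA"
    c2 = "GGGTTTAAACCCGGGTTTAAACCC"
    return GenomeSequence({"c1": c1, "c2": c2}), IntronRecord("c1", 10, 10 + len(intron), "+")


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(len(alphabet), size=n)])


@pytest.fixture
def dna_factory(rng):
    def make(n, alphabet="ACGT"):
        return random_dna(rng, n, alphabet)

    return make
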