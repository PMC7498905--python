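import numpy as np
import pytest

from methylradclone.digest import Contig, ContigSet


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def toy_genome():
    # one CCGG locus, one CCAGG locus, plenty of motif-free background
    return ContigSet(
        [
            Contig("c1", "TTTTTTTTTTTTTTCCGGTTTTTTTTTTTTTTTTTT"),
            Contig("c2", "AAAAAAAAAAAAAACCAGGAAAAAAAAAAAAAAAAA"),
        ]
    )


def random_motif_free_seq(rng, n):
    """Random sequence with no CCGG/CCWGG occurrence on either strand."""
    bad = ("CCGG", "CCAGG", "CCTGG")
    bases = np.array(list("ACGT"))
    while True:
        seq = "".join(bases[rng.integers(0, 4, size=n)])
        if not any(m in seq for m in bad):
            return seq
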