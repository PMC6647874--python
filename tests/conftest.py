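import pytest

from t3mine.genome import AnnotatedGenome, CDSFeature
from t3mine.simulate import GenomeSimConfig, generate_genome


def _toy_contig() -> str:
    # 600 nt, deterministic, free of hrp-box cores
    base = "ATCTGATCCATGAGTCAGTTACGGATTACCAGCTGCTAGCTAAGCTTGCATGCCTGCAGG"
    return (base * 10)[:600]


@pytest.fixture(scope="session")
def toy_genome() -> AnnotatedGenome:
    """Two-gene toy genome: one CDS per strand, in-frame, stop-terminated."""
    seq = list(_toy_contig())
    # + strand CDS at 101..130: ATG + 8 codons + TAA
    plus = "ATGAAAATTAGTGATCTGCTGAGCAGCTAA"
    seq[100:130] = plus
    # - strand CDS at 201..230 (coding sequence read on the minus strand)
    from t3mine.genome import reverse_complement

    minus = "ATGGACGAACTGAGCAGCAAACTGGTGTAA"
    seq[200:230] = reverse_complement(minus)
    contig = "".join(seq)
    return AnnotatedGenome(
        "toy",
        {"ctg1": contig},
        [
            CDSFeature("geneA", "ctg1", 101, 130, "+"),
            CDSFeature("geneB", "ctg1", 201, 230, "-"),
        ],
    )


@pytest.fixture(scope="session")
def sim_small():
    """A 300-kb planted genome shared across tests (fixed seed)."""
    genome, manifest = generate_genome(GenomeSimConfig(genome_length=300_000), seed=7)
    return genome, manifest
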