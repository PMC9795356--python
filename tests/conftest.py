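import io

import pytest

from elcap.annotation import GenomicInterval, TranscriptModel, parse_gene_models, read_chrom_sizes
from elcap.simulate import simulate_annotation


def make_transcript(
    gene_id="G0",
    transcript_id="T1",
    chrom="chr1",
    exons=((1000, 2000), (3000, 5000)),
    strand="+",
    support_level=1,
):
    return TranscriptModel(
        gene_id,
        transcript_id,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        support_level,
    )


@pytest.fixture
def plus_gene():
    return make_transcript()


@pytest.fixture
def minus_gene():
    return make_transcript(strand="-")


@pytest.fixture(scope="session")
def synthetic_annotation():
    """50 isolated genes on two chromosomes, parsed back into models."""
    gtf, sizes = simulate_annotation(
        50, [4_000_000, 4_000_000], seed=11, isolation_bp=50_000
    )
    genes = parse_gene_models(gtf.splitlines())
    genome = read_chrom_sizes(io.StringIO(sizes))
    return gtf, sizes, genes, genome
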