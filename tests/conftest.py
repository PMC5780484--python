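import pytest

from mantlelnc.annotation_io import AnnotationSet, GenomicInterval, TranscriptModel
from mantlelnc.synthetic_data import SyntheticSpec, generate_bundle


def tx(tid, chrom, strand, exons, gene=None, biotype="unknown"):
    """Shorthand transcript builder: exons as (start, end) pairs."""
    return TranscriptModel(
        tid,
        gene or f"G_{tid}",
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype=biotype,
    )


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic dataset shared across the suite."""
    return generate_bundle(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_ref():
    """A hand-built reference: one 3-exon coding gene on chr1:+ spanning
    [1000, 3000), plus an rRNA at [5000, 5300)."""
    coding = tx(
        "mrna1",
        "chr1",
        "+",
        [(1000, 1400), (1800, 2200), (2600, 3000)],
        gene="geneA",
        biotype="protein_coding",
    )
    rrna = tx("rrna1", "chr1", "+", [(5000, 5300)], gene="geneR", biotype="rRNA")
    return AnnotationSet([coding, rrna])
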