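import io

import numpy as np
import pytest

from archrep.genes import GeneModel
from archrep.intervals import GenomicInterval
from archrep.repeats import RepeatAnnotation, RepeatInstance


@pytest.fixture
def simple_gene() -> GeneModel:
    """Three-exon gene on chr1:+ spanning [100, 1100)."""
    return GeneModel(
        gene_id="G1",
        span=GenomicInterval("chr1", 100, 1100, "+"),
        exons=[
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 400, 600, "+"),
            GenomicInterval("chr1", 900, 1100, "+"),
        ],
    )


def random_gene(rng: np.random.Generator, gene_id: str = "G", max_span: int = 100_000) -> GeneModel:
    """A valid random gene with up to 50 (possibly overlapping) exons."""
    span_len = int(rng.integers(200, max_span))
    start = int(rng.integers(0, 10_000))
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 51))
    exons = []
    for _ in range(n_exons):
        s = start + int(rng.integers(0, span_len - 1))
        e = s + int(rng.integers(1, max(2, min(span_len - (s - start), 5000))))
        exons.append(GenomicInterval("chr1", s, min(e, start + span_len), strand))
    # anchor the first exon at the span start
    exons[0] = GenomicInterval(
        "chr1", start, start + min(span_len, max(1, exons[0].length)), strand
    )
    return GeneModel(
        gene_id=gene_id,
        span=GenomicInterval("chr1", start, start + span_len, strand),
        exons=exons,
    )


@pytest.fixture
def toy_annotation() -> RepeatAnnotation:
    return RepeatAnnotation(
        [
            RepeatInstance(GenomicInterval("chr1", 0, 60, "+"), "SINE/Alu", "AluY"),
            RepeatInstance(GenomicInterval("chr1", 40, 100, "+"), "SINE/Alu", "AluSx"),
            RepeatInstance(GenomicInterval("chr1", 200, 300, "-"), "LINE/L1", "L1M"),
        ]
    )


GTF_TEXT = """\
chr1\ttest\tgene\t101\t1100\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\ttest\texon\t401\t600\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\ttest\tgene\t2001\t2500\t.\t-\t.\tgene_id "G2"; gene_biotype "protein_coding";
chr1\ttest\texon\t2001\t2500\t.\t-\t.\tgene_id "G2"; gene_biotype "protein_coding";
chr1\ttest\tgene\t3001\t3500\t.\t+\t.\tgene_id "G3"; gene_biotype "lincRNA";
chr1\ttest\texon\t3001\t3200\t.\t+\t.\tgene_id "G3"; gene_biotype "lincRNA";
"""


@pytest.fixture
def gtf_stream():
    return io.StringIO(GTF_TEXT)
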