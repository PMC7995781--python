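"""Gene models and architectural quantities.

A gene's *exonic region* is the union of all its exons (across all
transcripts); its *intronic region* is the genomic span minus that union.
*Exonic content* — the fraction of the span covered by exons — is a
compactness measure: compact genes have exonic content near 1, genes with
long introns near 0.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import IO, Iterable, Union

import pandas as pd

from .intervals import GenomicInterval, RegionSet, subtract_intervals

__all__ = [
    "GeneModel",
    "GeneArchitecture",
    "GtfParseError",
    "GeneValidationError",
    "read_gene_models",
    "exonic_region",
    "intronic_region",
    "architecture",
    "architecture_table",
    "read_gene_set",
    "read_ortholog_map",
]


class GtfParseError(ValueError):
    """Raised on a malformed annotation line; message names the line number."""


class GeneValidationError(ValueError):
    """Raised when a gene's features violate the gene-model invariants."""


@dataclass
class GeneModel:
    """A stranded gene with its (merged or unmerged) exon intervals.

    Invariants: at least one exon; every exon inside the span; all exons on
    the gene's chromosome and strand.  Exons are stored sorted by start.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneValidationError(f"gene {self.gene_id}: no exons")
        chroms = {e.chrom for e in self.exons} | {self.span.chrom}
        strands = {e.strand for e in self.exons} | {self.span.strand}
        if len(chroms) > 1 or len(strands) > 1:
            raise GeneValidationError(
                f"gene {self.gene_id}: exons on multiple chromosomes or strands"
            )
        for e in self.exons:
            if not self.span.contains(e):
                raise GeneValidationError(
                    f"gene {self.gene_id}: exon {e.start}-{e.end} outside gene span "
                    f"{self.span.start}-{self.span.end}"
                )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand


@dataclass(frozen=True)
class GeneArchitecture:
    """Per-gene length decomposition: exonic + intronic = span."""

    gene_id: str
    chrom: str
    strand: str
    span_length: int
    exonic_length: int
    intronic_length: int
    exonic_content: float


def exonic_region(gene: GeneModel) -> RegionSet:
    """Union of the gene's exons as a merged :class:`RegionSet`."""
    return RegionSet.from_intervals(
        gene.chrom, gene.strand, [(e.start, e.end) for e in gene.exons]
    )


def intronic_region(gene: GeneModel) -> RegionSet:
    """Gene span minus the exonic region; empty for single-exon genes."""
    exonic = exonic_region(gene)
    introns = subtract_intervals((gene.span.start, gene.span.end), exonic.intervals)
    return RegionSet(chrom=gene.chrom, strand=gene.strand, intervals=introns)


def architecture(gene: GeneModel) -> GeneArchitecture:
    """Exonic/intronic lengths and exonic content for one gene."""
    exonic = exonic_region(gene)
    span_length = gene.span.length
    exonic_length = exonic.total_length
    return GeneArchitecture(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        span_length=span_length,
        exonic_length=exonic_length,
        intronic_length=span_length - exonic_length,
        exonic_content=exonic_length / span_length,
    )


def architecture_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Architecture of many genes as a DataFrame indexed by gene_id."""
    rows = [architecture(g).__dict__ for g in genes]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "strand",
            "span_length",
            "exonic_length",
            "intronic_length",
            "exonic_content",
        ],
    )
    return df.set_index("gene_id")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gene_models(
    source: Union[str, IO[str]],
    protein_coding_only: bool = True,
) -> dict[str, GeneModel]:
    """Read gene models from a GTF stream or path (ENSEMBL dialect).

    GTF coordinates are 1-based closed and converted to the internal
    0-based half-open convention.  Exons of all transcripts are pooled per
    gene (the exonic region later takes their union).  With
    ``protein_coding_only`` (default), genes whose ``gene_biotype``
    attribute is present and differs from ``protein_coding`` are dropped.

    Raises
    ------
    GtfParseError
        On a malformed line, naming the 1-based line number.
    GeneValidationError
        If an exon lies outside its gene's recorded span, naming the gene.
    """
    if isinstance(source, str):
        handle: IO[str] = open(source)
        close = True
    else:
        handle, close = source, False

    spans: dict[str, GenomicInterval] = {}
    biotypes: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            if start_i > end_i:
                raise GtfParseError(f"line {lineno}: start > end")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            if feature == "gene":
                spans[gene_id] = iv
                if "gene_biotype" in attributes:
                    biotypes[gene_id] = attributes["gene_biotype"]
            else:
                exons.setdefault(gene_id, []).append(iv)
    finally:
        if close:
            handle.close()

    models: dict[str, GeneModel] = {}
    for gene_id, gene_exons in exons.items():
        if protein_coding_only and biotypes.get(gene_id, "protein_coding") != "protein_coding":
            continue
        span = spans.get(gene_id)
        if span is None:
            # gene feature absent: span from exon extent
            span = GenomicInterval(
                gene_exons[0].chrom,
                min(e.start for e in gene_exons),
                max(e.end for e in gene_exons),
                gene_exons[0].strand,
            )
        models[gene_id] = GeneModel(gene_id=gene_id, span=span, exons=gene_exons)
    return models


def read_gene_set(source: Union[str, IO[str]]) -> list[str]:
    """One gene id per line; blank lines and '#' comments skipped."""
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def read_ortholog_map(source: Union[str, IO[str]]) -> dict[str, str]:
    """Plain two-column TSV (id_A, id_B) read verbatim into a dict."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
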