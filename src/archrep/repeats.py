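"""RepeatMasker annotation and per-gene repeat-density tables.

Repeat density of a region in family X is the fraction of the region's
bases covered by at least one instance of X on the qualifying strand.
Instances are merged within (family, strand) before counting, so nested or
overlapping RepeatMasker entries are never double-counted and density stays
in [0, 1].  "Sense" means the repeat strand equals the host gene's strand.

Families whose label contains a question mark (low-confidence calls) and
the Simple_repeat / Low_complexity classes are excluded on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .genes import GeneModel, exonic_region, intronic_region
from .intervals import GenomicInterval, RegionSet, merge_intervals, overlap_bp

__all__ = [
    "RepeatInstance",
    "RepeatAnnotation",
    "RepeatMaskerParseError",
    "read_repeatmasker",
    "family_overlap_bp",
    "density_table",
    "EXCLUDED_CLASSES",
]

EXCLUDED_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


class RepeatMaskerParseError(ValueError):
    """Raised on an unparsable annotation line; message names the line number."""


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated repeat copy with its class/family label."""

    interval: GenomicInterval
    family: str  # repClass/repFamily, e.g. "SINE/Alu"
    name: str = ""


def _family_excluded(family: str) -> bool:
    if "?" in family:
        return True
    rep_class = family.split("/", 1)[0]
    return rep_class in EXCLUDED_CLASSES or family in EXCLUDED_CLASSES


class RepeatAnnotation:
    """Repeat instances indexed by (chromosome, family).

    Retrieval returns merged (start, end) arrays per strand so overlap
    computations are linear merges of sorted disjoint interval lists.
    """

    def __init__(self, instances: Iterable[RepeatInstance]):
        self._instances: list[RepeatInstance] = []
        # (chrom, family, strand) -> merged ndarray of (start, end)
        self._merged: dict[tuple[str, str, str], np.ndarray] = {}
        raw: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
        for inst in instances:
            if _family_excluded(inst.family):
                continue
            self._instances.append(inst)
            key = (inst.interval.chrom, inst.family, inst.interval.strand)
            raw.setdefault(key, []).append((inst.interval.start, inst.interval.end))
        for key, pairs in raw.items():
            self._merged[key] = merge_intervals(pairs)

    @property
    def instances(self) -> list[RepeatInstance]:
        return list(self._instances)

    @property
    def families(self) -> list[str]:
        return sorted({i.family for i in self._instances})

    def get(self, chrom: str, family: str) -> list[RepeatInstance]:
        out = [
            i
            for i in self._instances
            if i.interval.chrom == chrom and i.family == family
        ]
        return sorted(out, key=lambda i: i.interval.start)

    def merged_intervals(self, chrom: str, family: str, strand: str) -> np.ndarray:
        return self._merged.get(
            (chrom, family, strand), np.empty((0, 2), dtype=np.int64)
        )

    def to_class_level(self) -> "RepeatAnnotation":
        """Collapse family granularity to the repeat class (before the '/')."""
        return RepeatAnnotation(
            RepeatInstance(
                interval=i.interval, family=i.family.split("/", 1)[0], name=i.name
            )
            for i in self._instances
        )


def _parse_out(handle: IO[str]) -> Iterable[RepeatInstance]:
    # RepeatMasker .out: 3 header lines, whitespace-separated columns,
    # strand "C" = complement, coordinates 1-based closed.
    for lineno, line in enumerate(handle, start=1):
        if lineno <= 3 or not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise RepeatMaskerParseError(
                f"line {lineno}: expected >=11 whitespace-separated fields"
            )
        try:
            chrom = fields[4]
            start = int(fields[5]) - 1
            end = int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            name = fields[9]
            family = fields[10]
        except ValueError as exc:
            raise RepeatMaskerParseError(f"line {lineno}: {exc}") from exc
        yield RepeatInstance(GenomicInterval(chrom, start, end, strand), family, name)


_RMSK_COLS = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]


def _parse_rmsk_tsv(handle: IO[str]) -> Iterable[RepeatInstance]:
    # UCSC rmsk-style TSV, 0-based half-open.
    df = pd.read_csv(handle, sep="\t", comment="#")
    missing = [c for c in _RMSK_COLS if c not in df.columns]
    if missing:
        raise RepeatMaskerParseError(f"rmsk TSV missing columns: {missing}")
    for row in df.itertuples(index=False):
        family = f"{row.repClass}/{row.repFamily}"
        yield RepeatInstance(
            GenomicInterval(str(row.genoName), int(row.genoStart), int(row.genoEnd), str(row.strand)),
            family,
            str(row.repName),
        )


def read_repeatmasker(
    source: Union[str, IO[str]], dialect: str = "rmsk_tsv"
) -> RepeatAnnotation:
    """Load repeat annotation from RepeatMasker ``out`` or UCSC ``rmsk_tsv``.

    Low-confidence families (containing '?'), Simple_repeat and
    Low_complexity are dropped.  Coordinates are converted to 0-based
    half-open (.out is 1-based closed; rmsk TSV already half-open).
    """
    if dialect not in ("out", "rmsk_tsv"):
        raise ValueError(f"unknown RepeatMasker dialect {dialect!r}")
    if isinstance(source, str):
        handle: IO[str] = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        parser = _parse_out if dialect == "out" else _parse_rmsk_tsv
        return RepeatAnnotation(parser(handle))
    finally:
        if close:
            handle.close()


def family_overlap_bp(
    region: RegionSet,
    family: str,
    orientation: str,
    gene_strand: str,
    annotation: RepeatAnnotation,
) -> int:
    """Bases of ``region`` covered by family instances in one orientation.

    ``orientation`` is ``"sense"`` (repeat strand == gene strand) or
    ``"antisense"``.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be sense or antisense, got {orientation!r}")
    if orientation == "sense":
        repeat_strand = gene_strand
    else:
        repeat_strand = "-" if gene_strand == "+" else "+"
    merged = annotation.merged_intervals(region.chrom, family, repeat_strand)
    if len(merged) == 0 or not region:
        return 0
    # binary-search the merged annotation per region interval: both sides are
    # sorted and disjoint, so only the [i, j) slice can overlap
    starts, ends = merged[:, 0], merged[:, 1]
    total = 0
    for s, e in region.intervals:
        i = int(np.searchsorted(ends, s, side="right"))
        j = int(np.searchsorted(starts, e, side="left"))
        if j > i:
            total += int(
                np.clip(np.minimum(ends[i:j], e) - np.maximum(starts[i:j], s), 0, None).sum()
            )
    return total


def density_table(
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    annotation: RepeatAnnotation,
    families: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene repeat density per (family, region, orientation) stratum.

    One row per gene x family x {exon, intron} x {sense, antisense}; strata
    with no overlap get density 0 so gene-set means are well defined.
    Genes with an empty intronic region emit no intron rows.
    """
    if isinstance(genes, Mapping):
        gene_list = list(genes.values())
    else:
        gene_list = list(genes)
    fams = sorted(families) if families is not None else annotation.families
    rows: list[tuple] = []
    for gene in gene_list:
        regions = {"exon": exonic_region(gene), "intron": intronic_region(gene)}
        for region_name, region in regions.items():
            region_length = region.total_length
            if region_length == 0:
                continue
            for family in fams:
                for orientation in ("sense", "antisense"):
                    ov = family_overlap_bp(
                        region, family, orientation, gene.strand, annotation
                    )
                    rows.append(
                        (
                            gene.gene_id,
                            family,
                            region_name,
                            orientation,
                            region_length,
                            ov,
                            ov / region_length,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "family",
            "region",
            "orientation",
            "region_length",
            "overlap_bp",
            "density",
        ],
    )
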