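"""Pyknon motif search, per-gene density, and repeat-family attribution.

Pyknons are recurring DNA motifs with copies both inside mRNA-coding
sequence and elsewhere in the genome; here they arrive as an input motif
list and are located by exhaustive exact search (overlapping occurrences
included).  Hits in exonic space partition motifs across gene groups
(Venn cells); genomic hits intersected with RepeatMasker instances assign
each motif to the repeat families it overlaps — possibly several.

Per-gene density is the number of distinct motifs of a chosen subset seen
in the gene's exons, per 10,000 bp of exonic length; an instance-based
per-1,000-bp variant is emitted in parallel because both normalizations
are in circulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel, exonic_region
from .intervals import GenomicInterval, merge_intervals
from .repeats import RepeatAnnotation

__all__ = [
    "PyknonMotif",
    "MotifHit",
    "GenePyknonProfile",
    "FamilyAttribution",
    "read_motifs",
    "find_motif_hits",
    "exonic_hit_table",
    "partition_motifs",
    "gene_density_profile",
    "attribute_to_families",
    "compare_density_groups",
    "compare_family_distributions",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PyknonMotif:
    motif_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if len(seq) < 6:
            raise ValueError(f"motif {self.motif_id}: length must be >= 6")
        if seq != seq.upper() or set(seq) - set("ACGT"):
            raise ValueError(f"motif {self.motif_id}: sequence must be uppercase ACGT")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class GenePyknonProfile:
    """Motif content of one gene's exonic space.

    density is distinct motifs per 10,000 bp of exonic length;
    density_alt is motif instances per 1,000 bp.
    """

    gene_id: str
    distinct_motifs: int
    instances: int
    exonic_length: int
    density: float
    density_alt: float


@dataclass
class FamilyAttribution:
    """Repeat-family memberships of a motif collection.

    A motif belongs to every family one of its genomic hits overlaps, so
    family percentages are computed over motifs and may sum above 100%.
    """

    motif_families: dict[str, set[str]]
    n_motifs: int

    @property
    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fams in self.motif_families.values():
            for fam in fams:
                counts[fam] = counts.get(fam, 0) + 1
        return dict(sorted(counts.items()))

    @property
    def family_percentages(self) -> dict[str, float]:
        return {f: 100.0 * c / self.n_motifs for f, c in self.family_counts.items()}


def read_motifs(source: Union[str, IO[str]]) -> list[PyknonMotif]:
    """Motif list TSV: motif_id <tab> sequence (or bare sequences)."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()
    motifs = []
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            motifs.append(PyknonMotif(f"pyk{i + 1}", parts[0].strip().upper()))
        else:
            motifs.append(PyknonMotif(parts[0].strip(), parts[1].strip().upper()))
    return motifs


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)  # step 1: overlapping occurrences count


def find_motif_hits(
    motifs: Iterable[PyknonMotif],
    sequences: Mapping[str, str],
    both_strands: bool = False,
) -> list[MotifHit]:
    """Every exact occurrence of every motif in the given sequences.

    Search is on the forward strand of each sequence (pyknons are
    strand-defined motifs); ``both_strands`` additionally reports
    reverse-complement matches on the ``-`` strand.  Ambiguous bases (N)
    never match because motifs are strict ACGT.
    """
    hits: list[MotifHit] = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        for motif in motifs:
            m = len(motif.sequence)
            for pos in _find_all(seq, motif.sequence):
                hits.append(MotifHit(motif.motif_id, GenomicInterval(chrom, pos, pos + m, "+")))
            if both_strands:
                rc = motif.sequence.translate(_COMPLEMENT)[::-1]
                for pos in _find_all(seq, rc):
                    hits.append(
                        MotifHit(motif.motif_id, GenomicInterval(chrom, pos, pos + m, "-"))
                    )
    return hits


def exonic_hit_table(
    hits: Iterable[MotifHit], genes: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Map hits to genes by exonic-region overlap (>= 1 bp).

    Returns a DataFrame with columns motif_id, gene_id, start, end; a hit
    overlapping the exons of several genes yields one row per gene.
    """
    rows = []
    exonic = {gid: exonic_region(g) for gid, g in genes.items()}
    for hit in hits:
        for gid, region in exonic.items():
            if region.chrom != hit.interval.chrom:
                continue
            starts = region.intervals[:, 0]
            ends = region.intervals[:, 1]
            if np.any((starts < hit.interval.end) & (hit.interval.start < ends)):
                rows.append((hit.motif_id, gid, hit.interval.start, hit.interval.end))
    return pd.DataFrame(rows, columns=["motif_id", "gene_id", "start", "end"])


def partition_motifs(
    gene_sets: Mapping[str, Iterable[str]],
    exonic_hits: pd.DataFrame,
    known_genes: Iterable[str] | None = None,
) -> dict[frozenset, set[str]]:
    """Venn partition of motif ids across named gene sets.

    A motif belongs to a set when it has >= 1 exonic hit in one of the
    set's genes; each Venn cell (frozenset of set names) maps to the
    motifs exclusive to exactly that combination.  Unknown gene ids in a
    set raise a warning and are skipped.
    """
    known = set(known_genes) if known_genes is not None else None
    per_set: dict[str, set[str]] = {}
    gene_to_motifs: dict[str, set[str]] = {}
    for row in exonic_hits.itertuples(index=False):
        gene_to_motifs.setdefault(row.gene_id, set()).add(row.motif_id)
    for name, ids in gene_sets.items():
        motifs: set[str] = set()
        for gid in ids:
            if known is not None and gid not in known:
                warnings.warn(f"gene set {name!r}: unknown gene id {gid!r} skipped")
                continue
            motifs |= gene_to_motifs.get(gid, set())
        per_set[name] = motifs
    all_motifs = set().union(*per_set.values()) if per_set else set()
    cells: dict[frozenset, set[str]] = {}
    for motif in all_motifs:
        members = frozenset(n for n, ms in per_set.items() if motif in ms)
        cells.setdefault(members, set()).add(motif)
    return cells


def gene_density_profile(
    gene_id: str,
    exonic_length: int,
    motif_subset: Iterable[str],
    exonic_hits: pd.DataFrame,
) -> GenePyknonProfile:
    """Distinct-motif and instance densities of one gene within a subset."""
    if exonic_length <= 0:
        raise ValueError(f"gene {gene_id}: exonic length must be positive")
    subset = set(motif_subset)
    mine = exonic_hits[
        (exonic_hits["gene_id"] == gene_id) & (exonic_hits["motif_id"].isin(subset))
    ]
    distinct = int(mine["motif_id"].nunique())
    instances = int(len(mine))
    return GenePyknonProfile(
        gene_id=gene_id,
        distinct_motifs=distinct,
        instances=instances,
        exonic_length=exonic_length,
        density=distinct / exonic_length * 10_000,
        density_alt=instances / exonic_length * 1_000,
    )


def attribute_to_families(
    hits: Iterable[MotifHit],
    annotation: RepeatAnnotation,
    motif_ids: Iterable[str] | None = None,
) -> FamilyAttribution:
    """Assign each motif to every repeat family any genomic hit overlaps.

    Overlap of >= 1 bp with an instance of a family, on either strand,
    suffices for membership.
    """
    hits = list(hits)
    universe = set(motif_ids) if motif_ids is not None else {h.motif_id for h in hits}
    # merged both-strand intervals per (chrom, family)
    merged: dict[tuple[str, str], np.ndarray] = {}
    chroms = {h.interval.chrom for h in hits}
    for chrom in chroms:
        for family in annotation.families:
            both = np.vstack(
                [
                    annotation.merged_intervals(chrom, family, "+"),
                    annotation.merged_intervals(chrom, family, "-"),
                ]
            )
            if len(both):
                merged[(chrom, family)] = merge_intervals(both)
    motif_families: dict[str, set[str]] = {m: set() for m in universe}
    for hit in hits:
        if hit.motif_id not in motif_families:
            continue
        for (chrom, family), ivals in merged.items():
            if chrom != hit.interval.chrom:
                continue
            j = np.searchsorted(ivals[:, 0], hit.interval.end)
            if j > 0 and ivals[j - 1, 1] > hit.interval.start:
                motif_families[hit.motif_id].add(family)
    return FamilyAttribution(motif_families=motif_families, n_motifs=len(universe))


def compare_density_groups(densities_a, densities_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-gene motif densities."""
    a = np.asarray(list(densities_a), dtype=float)
    b = np.asarray(list(densities_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all densities tied; Mann-Whitney test degenerate, p = 1")
        return float(a.size * b.size / 2.0), 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def compare_family_distributions(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int], min_expected: float = 1.0
) -> tuple[float, float]:
    """Chi-squared test comparing two family count vectors.

    Families are aligned on the union of categories; rare families whose
    pooled count would leave an expected cell below ``min_expected`` are
    pooled into an "other" category.
    """
    families = sorted(set(counts_a) | set(counts_b))
    a = np.array([counts_a.get(f, 0) for f in families], dtype=float)
    b = np.array([counts_b.get(f, 0) for f in families], dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both count vectors must have positive totals")
    table = np.vstack([a, b])
    # pool rare categories so expected counts stay above the floor
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    rare = expected.min(axis=0) < min_expected
    if rare.any() and (~rare).any():
        pooled = table[:, rare].sum(axis=1, keepdims=True)
        table = np.hstack([table[:, ~rare], pooled])
    stat, p, _, _ = stats.chi2_contingency(table)
    return float(stat), float(p)
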