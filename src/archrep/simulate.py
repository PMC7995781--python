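"""Synthetic genomes, repeat annotations, motifs and expression cohorts.

Every generator is deterministic given a seed, and all randomness flows
from that seed through named substreams, so each output is individually
reproducible.  The genome generator plants known group-level contrasts —
length distributions per gene group and repeat density per
(family, region, orientation) stratum — so the downstream density,
enrichment and length-bias machinery has a ground truth to recover.
Repeat instances are placed non-overlapping inside their target region
(no spill-over across exon/intron boundaries), keeping stratum densities
independently controllable; per-gene densities are jittered around the
group target so gene-to-gene variance is realistic rather than degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genes import GeneModel
from .intervals import GenomicInterval
from .repeats import RepeatAnnotation, RepeatInstance

__all__ = [
    "GeneGroupSpec",
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "SyntheticExpressionSpec",
    "SyntheticMotifSpec",
    "generate_genome",
    "generate_expression",
    "generate_motifs",
    "generate_binary_profiles",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# substream tags (kept small so derived seeds stay below 2**31)
_STREAMS = {"genes": 11, "repeats": 12, "sequence": 13, "motifs": 14, "expression": 15}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class GeneGroupSpec:
    """One gene group with its length distributions and repeat targets.

    Exon count per gene is geometric with the given mean (support >= 1);
    exon and intron lengths are log-normal in bp.  ``repeat_density`` maps
    (family, region, orientation) -> target coverage fraction of that
    stratum, e.g. ("SINE/Alu", "intron", "sense") -> 0.3.
    """

    name: str
    n_genes: int
    exon_count_mean: float = 5.0
    exon_length_meanlog: float = math.log(150.0)
    exon_length_sdlog: float = 0.5
    intron_length_meanlog: float = math.log(1500.0)
    intron_length_sdlog: float = 0.8
    repeat_density: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.exon_count_mean < 1:
            raise ValueError("n_genes must be positive and exon_count_mean >= 1")
        if self.exon_length_sdlog <= 0 or self.intron_length_sdlog <= 0:
            raise ValueError("length distribution scales must be positive")
        for key, d in self.repeat_density.items():
            if not 0 <= d <= 0.9:
                raise ValueError(f"target density for {key} must be in [0, 0.9], got {d}")
            if key[1] not in ("exon", "intron") or key[2] not in ("sense", "antisense"):
                raise ValueError(f"bad stratum key {key}")


@dataclass
class SyntheticGenomeSpec:
    groups: list[GeneGroupSpec]
    n_chromosomes: int = 1
    intergenic_gap: int = 300
    density_jitter: float = 0.3  # per-gene multiplier U(1-j, 1+j) on the group target
    repeat_unit_length: int = 300  # typical planted instance size, bp
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one gene group required")
        if not 0 <= self.density_jitter < 1:
            raise ValueError("density_jitter must be in [0, 1)")


@dataclass
class SyntheticGenome:
    """Generated annotation with planted ground truth."""

    genes: dict[str, GeneModel]
    annotation: RepeatAnnotation
    membership: dict[str, str]  # gene_id -> group name
    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None
    spec: SyntheticGenomeSpec

    def group_genes(self, name: str) -> list[str]:
        return sorted(g for g, grp in self.membership.items() if grp == name)

    # -- text writers ------------------------------------------------------

    def to_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for gid in sorted(self.genes):
                g = self.genes[gid]
                attrs = f'gene_id "{gid}"; gene_biotype "protein_coding";'
                fh.write(
                    f"{g.chrom}\tarchrep\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for e in g.exons:
                    fh.write(
                        f"{g.chrom}\tarchrep\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )

    def to_rmsk_tsv(self, path: str) -> None:
        rows = []
        for inst in self.annotation.instances:
            rep_class, _, rep_family = inst.family.partition("/")
            rows.append(
                (
                    inst.interval.chrom,
                    inst.interval.start,
                    inst.interval.end,
                    inst.interval.strand,
                    inst.name,
                    rep_class,
                    rep_family or rep_class,
                )
            )
        pd.DataFrame(
            rows,
            columns=["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"],
        ).to_csv(path, sep="\t", index=False)

    def to_fasta(self, path: str) -> None:
        if self.sequences is None:
            raise ValueError("genome generated without sequence")
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in sorted(self.sequences.items())
        ]
        SeqIO.write(records, path, "fasta")

    def to_membership_tsv(self, path: str) -> None:
        pd.DataFrame(
            sorted(self.membership.items()), columns=["gene_id", "group"]
        ).to_csv(path, sep="\t", index=False)


def _draw_gene_structure(
    rng: np.random.Generator, group: GeneGroupSpec
) -> tuple[list[int], list[int]]:
    n_exons = int(rng.geometric(1.0 / group.exon_count_mean))
    exon_lengths = np.maximum(
        30, rng.lognormal(group.exon_length_meanlog, group.exon_length_sdlog, n_exons)
    ).astype(int)
    intron_lengths = np.maximum(
        60,
        rng.lognormal(group.intron_length_meanlog, group.intron_length_sdlog, max(0, n_exons - 1)),
    ).astype(int)
    return list(exon_lengths), list(intron_lengths)


def _place_in_interval(
    rng: np.random.Generator, start: int, end: int, target_bp: int, unit: int
) -> list[tuple[int, int]]:
    """Non-overlapping segments covering ~target_bp of [start, end)."""
    length = end - start
    target_bp = min(target_bp, length)
    if target_bp <= 0:
        return []
    k = max(1, int(round(target_bp / unit)))
    sizes = np.full(k, target_bp // k, dtype=int)
    sizes[: target_bp % k] += 1
    free = length - target_bp
    gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1))) if free > 0 else np.zeros(k + 1, int)
    out = []
    cursor = start
    for i in range(k):
        cursor += int(gaps[i])
        if sizes[i] > 0:
            out.append((cursor, cursor + int(sizes[i])))
        cursor += int(sizes[i])
    return out


def generate_genome(
    spec: SyntheticGenomeSpec, with_sequence: bool = True
) -> SyntheticGenome:
    """Generate gene models, repeat annotation and (optionally) sequence.

    Gene structures are drawn from each group's length distributions;
    repeat instances are placed to hit each group's per-stratum target
    density up to the per-gene jitter, whose mean is 1 so realized group
    means land within a few percent of the target.
    """
    gene_rng = _rng(spec.seed, "genes")
    rep_rng = _rng(spec.seed, "repeats")

    genes: dict[str, GeneModel] = {}
    membership: dict[str, str] = {}
    instances: list[RepeatInstance] = []
    cursors = {f"chr{i + 1}": 0 for i in range(spec.n_chromosomes)}
    chrom_names = list(cursors)

    gene_no = 0
    for group in spec.groups:
        for _ in range(group.n_genes):
            gene_no += 1
            gid = f"G{gene_no:05d}"
            chrom = chrom_names[gene_no % spec.n_chromosomes]
            exon_lengths, intron_lengths = _draw_gene_structure(gene_rng, group)
            strand = "+" if gene_rng.random() < 0.5 else "-"
            start = cursors[chrom] + spec.intergenic_gap
            pos = start
            exons: list[GenomicInterval] = []
            exon_pairs: list[tuple[int, int]] = []
            intron_pairs: list[tuple[int, int]] = []
            for i, el in enumerate(exon_lengths):
                exons.append(GenomicInterval(chrom, pos, pos + el, strand))
                exon_pairs.append((pos, pos + el))
                pos += el
                if i < len(intron_lengths):
                    intron_pairs.append((pos, pos + intron_lengths[i]))
                    pos += intron_lengths[i]
            span = GenomicInterval(chrom, start, pos, strand)
            cursors[chrom] = pos
            genes[gid] = GeneModel(gene_id=gid, span=span, exons=exons)
            membership[gid] = group.name

            regions = {"exon": exon_pairs, "intron": intron_pairs}
            for (family, region, orientation), target in sorted(group.repeat_density.items()):
                if target <= 0:
                    continue
                jitter = 1.0 + spec.density_jitter * (2 * rep_rng.random() - 1)
                d_gene = min(0.95, target * jitter)
                rep_strand = (
                    strand
                    if orientation == "sense"
                    else ("-" if strand == "+" else "+")
                )
                for (s, e) in regions[region]:
                    want = int(round(d_gene * (e - s)))
                    for (rs, re_) in _place_in_interval(
                        rep_rng, s, e, want, spec.repeat_unit_length
                    ):
                        instances.append(
                            RepeatInstance(
                                GenomicInterval(chrom, rs, re_, rep_strand),
                                family,
                                name=family.split("/")[-1],
                            )
                        )

    chrom_lengths = {c: cursors[c] + spec.intergenic_gap for c in chrom_names}
    sequences = None
    if with_sequence:
        seq_rng = _rng(spec.seed, "sequence")
        sequences = {}
        for chrom, length in chrom_lengths.items():
            codes = seq_rng.integers(0, 4, size=length, dtype=np.uint8)
            sequences[chrom] = _BASES[codes].tobytes().decode()

    return SyntheticGenome(
        genes=genes,
        annotation=RepeatAnnotation(instances),
        membership=membership,
        chrom_lengths=chrom_lengths,
        sequences=sequences,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# motifs


@dataclass
class SyntheticMotifSpec:
    """Motif list with planted genomic/exonic occurrences.

    The first ``n_in_families`` motifs are each planted inside an instance
    of one of ``families`` (cycled) *and* in one exon; the next motifs get
    an exonic placement only; ``n_unplaced`` motifs are never planted.
    """

    n_motifs: int = 30
    length_range: tuple[int, int] = (16, 20)
    families: tuple[str, ...] = ()
    n_in_families: int = 0
    n_unplaced: int = 0
    seed: int = 0


def generate_motifs(
    genome: SyntheticGenome, spec: SyntheticMotifSpec
) -> tuple[list, pd.DataFrame]:
    """Plant motifs into the genome sequence; returns (motifs, truth table).

    Mutates ``genome.sequences`` in place (placements are merged into the
    sequence).  The truth table records, per planted occurrence, the
    motif, its location, the context (exon of which gene / repeat family /
    none), so searches and attributions can be checked exactly.
    """
    if genome.sequences is None:
        raise ValueError("motif planting needs a genome generated with sequence")
    from .pyknon import PyknonMotif

    rng = _rng(spec.seed, "motifs")
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}

    def free(chrom: str, start: int, end: int) -> bool:
        return all(e <= start or end <= s for s, e in used[chrom])

    def plant(chrom: str, start: int, seq: str) -> None:
        seqs[chrom][start : start + len(seq)] = seq.encode()
        used[chrom].append((start, start + len(seq)))

    gene_ids = sorted(genome.genes)
    truth_rows = []
    motifs = []
    for i in range(spec.n_motifs):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))
        motif_id = f"pyk{i + 1:03d}"
        motifs.append(PyknonMotif(motif_id, seq))
        if i >= spec.n_motifs - spec.n_unplaced:
            continue
        # one exonic placement
        for _ in range(200):
            gid = gene_ids[int(rng.integers(len(gene_ids)))]
            gene = genome.genes[gid]
            exon = gene.exons[int(rng.integers(len(gene.exons)))]
            if exon.length < length:
                continue
            pos = exon.start + int(rng.integers(exon.length - length + 1))
            if free(gene.chrom, pos, pos + length):
                plant(gene.chrom, pos, seq)
                truth_rows.append((motif_id, gene.chrom, pos, "exon", gid, ""))
                break
        # optional placement inside a repeat instance of a chosen family
        if spec.families and i < spec.n_in_families:
            family = spec.families[i % len(spec.families)]
            candidates = [
                inst
                for inst in genome.annotation.instances
                if inst.family == family and inst.interval.length >= length
            ]
            rng.shuffle(candidates)
            for inst in candidates:
                pos = inst.interval.start + int(
                    rng.integers(inst.interval.length - length + 1)
                )
                if free(inst.interval.chrom, pos, pos + length):
                    plant(inst.interval.chrom, pos, seq)
                    truth_rows.append(
                        (motif_id, inst.interval.chrom, pos, "repeat", "", family)
                    )
                    break

    genome.sequences = {c: b.decode() for c, b in seqs.items()}
    truth = pd.DataFrame(
        truth_rows, columns=["motif_id", "chrom", "start", "context", "gene_id", "family"]
    )
    return motifs, truth


# ---------------------------------------------------------------------------
# expression


@dataclass
class SyntheticExpressionSpec:
    """Expression cohort with planted tissue markers and housekeeping genes.

    Marker genes of a tissue are elevated by ``marker_fold`` in that
    tissue's samples only; housekeeping genes are high everywhere; the
    rest draw a shared baseline.  Noise is multiplicative log-normal with
    scale ``sigma``.
    """

    tissues: tuple[str, ...] = ("tissueA", "tissueB")
    samples_per_tissue: int = 10
    n_genes: int = 500
    markers_per_tissue: int = 20
    n_housekeeping: int = 20
    baseline_meanlog: float = math.log(10.0)
    baseline_sdlog: float = 1.0
    marker_fold: float = 4.0
    sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        needed = len(self.tissues) * self.markers_per_tissue + self.n_housekeeping
        if needed > self.n_genes:
            raise ValueError("marker + housekeeping genes exceed n_genes")


def generate_expression(
    spec: SyntheticExpressionSpec, gene_ids: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Returns (matrix genes x samples, labels sample -> tissue, truth).

    Truth rows: gene_id, role ("marker" / "housekeeping"), tissue (empty
    for housekeeping).  Marker sets of different tissues are disjoint.
    """
    rng = _rng(spec.seed, "expression")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != spec.n_genes:
            raise ValueError("gene_ids length must equal n_genes")

    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_genes)
    samples = [
        f"{t}_s{j + 1:02d}" for t in spec.tissues for j in range(spec.samples_per_tissue)
    ]
    labels = pd.Series(
        [t for t in spec.tissues for _ in range(spec.samples_per_tissue)],
        index=samples,
        name="tissue",
    )

    marker_of: dict[str, str] = {}
    truth_rows = []
    cursor = 0
    for tissue in spec.tissues:
        for _ in range(spec.markers_per_tissue):
            marker_of[gene_ids[cursor]] = tissue
            truth_rows.append((gene_ids[cursor], "marker", tissue))
            cursor += 1
    for _ in range(spec.n_housekeeping):
        baseline[cursor] = math.exp(spec.baseline_meanlog + 2.0)
        truth_rows.append((gene_ids[cursor], "housekeeping", ""))
        cursor += 1

    mean = np.tile(baseline[:, None], (1, len(samples)))
    for gi, gid in enumerate(gene_ids):
        tissue = marker_of.get(gid)
        if tissue is not None:
            mean[gi, (labels == tissue).to_numpy()] *= spec.marker_fold
    noise = rng.lognormal(0.0, spec.sigma, size=mean.shape)
    matrix = pd.DataFrame(mean * noise, index=gene_ids, columns=samples)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "role", "tissue"])
    return matrix, labels, truth


def generate_binary_profiles(
    n_tissues: int = 3,
    samples_per_tissue: int = 60,
    n_genes: int = 500,
    markers_per_tissue: int = 10,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Boolean expression profiles with disjoint tissue markers.

    Marker genes are expressed only in their own tissue; non-marker genes
    are expressed with a per-gene probability shared by all tissues
    (uninformative); finally each bit flips with ``flip_prob``
    (label-independent noise).  Returns (binary, labels, markers).
    """
    rng = _rng(seed, "expression")
    tissues = [f"T{i + 1}" for i in range(n_tissues)]
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"{t}_s{j + 1:02d}" for t in tissues for j in range(samples_per_tissue)]
    labels = pd.Series(
        [t for t in tissues for _ in range(samples_per_tissue)], index=samples, name="tissue"
    )
    values = np.zeros((n_genes, len(samples)), dtype=bool)
    markers: dict[str, list[str]] = {}
    cursor = 0
    for t in tissues:
        markers[t] = gene_ids[cursor : cursor + markers_per_tissue]
        values[cursor : cursor + markers_per_tissue, (labels == t).to_numpy()] = True
        cursor += markers_per_tissue
    background_p = rng.uniform(0.2, 0.8, size=n_genes - cursor)
    values[cursor:] = rng.random((n_genes - cursor, len(samples))) < background_p[:, None]
    flips = rng.random(values.shape) < flip_prob
    values ^= flips
    return pd.DataFrame(values, index=gene_ids, columns=samples), labels, markers
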