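# archrep

Gene sets that change expression together often share *architecture*: genes
highly expressed in proliferative or pluripotent states tend to be compact
(short introns, high exonic content) with introns rich in SINE
retroelements (Alu in primates, B elements in rodents), while genes that
establish tissue identity tend to have long, repeat-poor introns.
`archrep` provides the statistical machinery to test such claims for any
gene set against any background, plus a synthetic-genome generator with
planted ground truth so every stage of the pipeline can be validated
end-to-end without downloading any cohort.

It is aimed at computational biologists who have a gene annotation (GTF),
a RepeatMasker annotation, expression matrices, and one or more gene sets
of interest (e.g. up/down-regulated genes from a differential analysis).

## What it computes

**Gene architecture.** For each gene, the *exonic region* is the union of
all its exons, the *intronic region* is the genomic span minus that union,
and the *exonic content* is the fraction of the span covered by exons
(a compactness measure). A 132 kb gene with 4.5 kb of exons has exonic
content 4500/132000 ≈ 3%.

**Repeat density and Monte Carlo enrichment.** The density of a region in
repeat family *F* (e.g. `SINE/Alu`) is the fraction of its bases covered by
instances of *F*, computed separately for exons/introns and for
sense/antisense orientation relative to the host gene. For a target gene
set *T* and background *B*, the observed mean density d̄(T) is compared with
the null distribution of d̄(S) over 10,000 random subsets S ⊂ B with
|S| = |T| (sampling without replacement):

    Z = ( d̄(T) − E[d̄(S)] ) / sd[d̄(S)]

A stratum is called enriched (Z > 0) or depleted (Z < 0) when |Z| ≥ 2 and
the Benjamini–Hochberg FDR of its empirical two-sided Monte Carlo p-value,
corrected across all (family × region × orientation) strata, is ≤ 5%.
A Kolmogorov–Smirnov test of the per-gene density distributions is
reported alongside.

**Length-bias curves.** For a measured quantity (exonic length, intronic
length, exonic content) the curve Δ(x) = F_background(x) − F_set(x) is
evaluated on the pooled values, so a set shifted towards larger values is
positive everywhere; max|Δ| is exactly the two-sample KS statistic. A
3-point moving average is available for display; statistics always use the
unsmoothed curve.

**Pyknon motifs.** Input motif lists are located by exhaustive exact
search (overlapping occurrences included), partitioned across gene sets by
exonic occurrence (Venn cells), normalized per gene as distinct motifs per
10 kb of exonic length (instances per 1 kb in parallel), and attributed to
every repeat family any genomic occurrence overlaps. Group comparisons use
the Mann–Whitney U test (densities) and the chi-squared test (family
distributions).

**Differential expression utilities.** Quantile/threshold filters,
fold-change calls, a seeded two-sided permutation test on
variance-stabilized mean differences (statistics pooled across genes,
SAM-style), within-sample rank normalization (rank 1 = highest) for
cross-platform comparisons, and the hypergeometric overlap test.

**Binarized-expression tissue signatures.** Per sample, genes above an
abundance floor are candidates and the top half are marked "expressed";
widely expressed and uninformative genes are removed; a linear SVM is
trained per tissue pair on the boolean features with stratified 10-fold
cross-validation; samples are assigned by voting (share < 0.5 → "Other");
the per-gene variable importance VI_g = mean over pairwise models of w_g²
ranks the signature genes.

## Worked example

Simulate a genome where a 100-gene group has short introns tiled with
sense-strand Alu at twice the background density, then test that group:

```python
from archrep.simulate import GeneGroupSpec, SyntheticGenomeSpec, generate_genome
from archrep.repeats import density_table
from archrep.enrichment import MonteCarloEnrichment, MCConfig
from archrep.genes import architecture_table
from archrep.length_bias import cumulative_delta

spec = SyntheticGenomeSpec(
    groups=[
        GeneGroupSpec(name="up", n_genes=100, intron_length_meanlog=6.2,
                      repeat_density={("SINE/Alu", "intron", "sense"): 0.30,
                                      ("SINE/Alu", "intron", "antisense"): 0.10}),
        GeneGroupSpec(name="background", n_genes=300,
                      repeat_density={("SINE/Alu", "intron", "sense"): 0.15,
                                      ("SINE/Alu", "intron", "antisense"): 0.10}),
    ],
    seed=42,
)
genome = generate_genome(spec, with_sequence=False)
densities = density_table(genome.genes, genome.annotation)
results = MonteCarloEnrichment(densities, genome.group_genes("up"),
                               sorted(genome.genes),
                               MCConfig(iterations=10_000, seed=42)).fit()
print(results.summary())

arch = architecture_table(genome.genes.values())
up = genome.group_genes("up")
curve = cumulative_delta(arch.loc[up, "intronic_length"], arch["intronic_length"])
print(f"intronic length: KS={curve.ks_statistic:.3f}  p={curve.ks_p:.2e}  "
      f"set median={curve.set_median:.0f} bp  background median={curve.background_median:.0f} bp")
```

Output:

```
Monte Carlo repeat-density enrichment
  target genes:      100
  background genes:  400
  iterations:        10000
  seed:              42
  call rule:         |Z| >= 2.0, FDR <= 0.05

  family region orientation  observed_mean     z    fdr  significant
SINE/Alu   exon   antisense              0   NaN    NaN        False
SINE/Alu   exon       sense              0   NaN    NaN        False
SINE/Alu intron   antisense         0.1019 1.055 0.2884        False
SINE/Alu intron       sense         0.2962 15.12 0.0004         True

intronic length: KS=0.225  p=4.86e-04  set median=1999 bp  background median=3610 bp
```

Only the planted stratum (sense Alu in introns, Z = +15.1) is significant;
the exon strata carry no repeats and are non-evaluable (NaN), and the
antisense stratum — identical in both groups by construction — stays at
|Z| ≈ 1. The planted intron shortening shows up as a right-shifted
background (set median 2.0 kb vs 3.6 kb, KS p < 10⁻³).

The same analyses are scriptable from the shell:

```
archrep density    --gtf genes.gtf --rmsk repeats.tsv --dialect rmsk_tsv --out density.tsv
archrep enrich     --densities density.tsv --targets up.txt --background all.txt \
                   --iterations 10000 --seed 7 --out enrichment.tsv
archrep lengthbias --arch architecture.tsv --set up.txt --background all.txt \
                   --measure intronic_length --out curve.tsv
archrep run        --config pipeline.yaml --analysis bias
```

Each pipeline run writes a JSON manifest (parameters, seed, library
versions) sufficient to reproduce every output byte-identically.

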