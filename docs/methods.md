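# Methods

This note records the statistical procedures implemented in `archrep`,
the defaults they ship with, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open; readers convert on
ingestion (GTF and RepeatMasker `.out` are 1-based closed, UCSC rmsk TSV
is already half-open, `.out` strand `C` means complement). Interval sets
are kept fully merged — sorted, disjoint, non-adjacent — so lengths add
and coverage fractions are true fractions. Genes with exons on more than
one chromosome or strand are rejected. When a gene has several
transcripts, its exon set is the union of all transcript exons; the
exonic region is the merged union, the intronic region its complement
within the span. These operations are validated against per-base boolean
masks for spans up to 100 kb.

## Repeat density

Density of a region in family F (granularity `repClass/repFamily`,
collapsible to class) is overlap_bp / region_length, with instances
merged within (family, strand) before counting so nested or overlapping
RepeatMasker entries never push density above 1. The alternative —
summing raw instance lengths — is not a coverage fraction and was
rejected. "Sense" means the repeat strand equals the host gene's strand.
Families containing `?` (low-confidence) and the Simple_repeat /
Low_complexity classes are excluded at parse time. Strata a gene lacks
entirely (no repeats) are emitted with density 0 so set means are well
defined; genes without introns emit no intron rows.

## Monte Carlo enrichment

For target T ⊆ background B, each of `iterations` (default 10,000)
resamples draws |T| genes from B without replacement; the same resampled
gene subsets are reused across all strata, mirroring a per-iteration
"random choice of genes". Without replacement was chosen because the
background is finite and the null should be the subset distribution, not
a bootstrap. Per stratum:

* Z = (observed mean − null mean) / null SD (sample SD, ddof = 1);
  positive Z means denser than chance.
* empirical two-sided p = 2 · min(tail ranks), with the +1/(N+1)
  correction, capped at 1;
* a two-sample KS test of per-gene density distributions is reported
  alongside (it answers a different question — distribution shape rather
  than mean shift — and is never used for calling);
* BH-FDR is applied jointly across all evaluable strata of one
  comparison, on the Monte Carlo p (the KS FDR is emitted in parallel);
* significant ⇔ |Z| ≥ 2 and FDR ≤ 5% (both defaults configurable).

Strata whose null SD is zero (e.g. a family absent everywhere) are
flagged non-evaluable, excluded from the FDR family, and never
significant. Fixing the seed makes the whole table bit-reproducible.
The heatmap matrix keeps only families with at least one |Z| ≥ 2 cell.

Calibration: on null targets the |Z| ≥ 2 rate is close to the two-sided
normal tail (0.0455); the acceptance suite checks 500 null draws fall in
[0.025, 0.07]. Note that with several evaluable strata the per-run
probability that *some* null stratum clears both gates is a few percent —
a specificity experiment over 20 runs is expected to show an occasional
extra call; this is a property of the thresholds, not a defect.

## Length-bias curves

Δ(x) = F_background(x) − F_set(x) on the pooled sorted unique values
(exact empirical CDFs, right-continuous). The sign convention makes a set
shifted towards larger values positive. max|Δ| equals the two-sample KS
statistic by construction; the KS p-value is exact for samples up to 50
and asymptotic above. The 3-point moving average (edge windows shrink to
2 points, output length preserved) is display-only; all statistics use
the unsmoothed curve.

## Pyknon analysis

Motif search is exact, case-normalized, forward-strand (pyknons are
strand-defined motifs; `both_strands=True` adds reverse-complement
matches), and counts overlapping occurrences; `N` never matches because
motifs are strict ACGT. Per-gene density is distinct motifs of a chosen
subset per 10,000 bp of exonic length; an instance-based per-1,000-bp
variant is computed in parallel because both normalizations are in
circulation, and the two can rank genes differently — users should state
which they report. Family attribution requires ≥ 1 bp overlap of any
genomic occurrence with an instance of the family, on either strand;
a motif may belong to several families, so family percentages are over
motifs and may sum above 100%. Rare families are pooled before the
chi-squared comparison so expected counts stay above 1.

## Differential expression

The permutation test statistic is d = (mean_B − mean_A) / (s + s0) with
s the pooled per-gene SD and s0 the median of all s (variance
stabilization, preventing low-variance genes from dominating). Labels
are permuted jointly across genes; when the requested permutation count
reaches the number of distinct label assignments the test enumerates them
all. Permuted statistics are pooled across genes into one null: the
stabilized statistics are exchangeable, and pooling gives p-value
resolution 1/(permutations × genes) — without it, small designs (5 vs 5
has only 252 assignments) can never clear a 5% BH-FDR regardless of
effect size. The pooled null is slightly conservative when a few genes
carry extreme effects, since their partially-mixed permuted statistics
fatten the tail. BH-FDR at 5% (1% for rank-based runs) splits calls into
up/down by sign.

Rank normalization assigns rank 1 to the highest-expressed gene per
sample, ties averaged; it makes the analysis invariant to any
per-sample strictly increasing transform, which is the point of using it
across platforms. Fold-change calls add a 0.1 pseudo-count to group
means. Quantile filters use floor counts with (mean, gene id) ordering so
ties at the cutoff are deterministic; the mean-threshold filter is
strict (> 2, so a gene at exactly 2 is removed) and idempotent — the
fraction-based filters are deliberately not, since each application
removes a fraction of what remains. The hypergeometric overlap p is the
upper tail P(X ≥ |A∩B|).

## Tissue signatures from binarized expression

Binarization: per sample, genes with abundance strictly above 2 (FPKM-like
units) are candidates; the k = round-half-up(0.5 · #candidates) most
abundant candidates are "expressed" (ties broken by abundance then gene
id). Genes expressed in > 90% of samples within *every* tissue are
"widely expressed" and excluded from learning. The uninformative filter
removes genes whose not-expressed fraction is below 50% in every tissue;
read literally this subsumes the widely-expressed rule — both rules are
implemented as stated, with an `overall` mode switch, and the package
applies widely-expressed flagging and the literal filter independently
rather than resolving the redundancy.

Classification is one-vs-one: a linear SVM (C = 1) per tissue pair on the
boolean features, stratified seeded 10-fold cross-validation, prediction
by voting with probability = vote share = votes/(n_tissues − 1); a share
strictly below 0.5 sends the sample to "Other" (a share of exactly 0.5
keeps the tissue). The confusion report averages per-fold row
percentages. VI_g is the mean of squared hyperplane weights over all
pairwise models from a final fit on all samples; VI is invariant to
sample/gene order up to the SMO optimizer's convergence tolerance
(relative differences ~10⁻⁴ are expected).

## Synthetic data

The generator emulates the contrasts the pipeline is meant to detect:
gene groups with geometric exon counts and log-normal exon/intron lengths
(defaults: mean 5 exons, exon median 150 bp, intron median 1.5 kb —
typical mammalian orders of magnitude), and per-group target repeat
densities per (family, region, orientation) stratum. Instances (~300 bp
units, Alu-sized) are placed non-overlapping inside their target region
with multinomial gaps, never spilling across exon/intron boundaries, so
stratum densities are independently controllable; per-gene targets are
jittered by U(0.7, 1.3) so gene-to-gene density variance is realistic
rather than degenerate. Realized group means land within a few percent
of target. Motif planting overwrites sequence at recorded positions
(exonic, inside chosen repeat-family instances, or not at all) with
collision-free bookkeeping; default motif lengths 16–20 make accidental
occurrences in megabase-scale sequence vanishingly rare. Expression
cohorts plant disjoint tissue markers (fold 4 by default) and
housekeeping genes over a log-normal baseline with multiplicative
log-normal noise (σ = 0.4); a separate boolean-profile generator plants
disjoint marker genes and flips bits at 5% for classifier experiments.
All randomness descends from a single seed through named substreams, so
every artifact is individually reproducible and byte-identical across
reruns.

What passing these tests shows: the statistics recover planted effects of
realistic size and calibrate correctly under their own nulls. What they
do not show: robustness to properties of real genomes that the generator
deliberately omits — GC structure, repeat age/divergence, overlapping
genes, isoform complexity, correlated expression noise, batch effects.

## Problem sizes and numerical choices

Default test and acceptance workloads use 400–600-gene genomes,
10,000-iteration Monte Carlo runs, 500-replicate null calibrations at
1,000 iterations, 1 Mb motif-search fixtures, and a 180-sample
3-tissue classifier cohort — sizes chosen so the full validation runs in
about a minute while keeping every statistical check well-powered.
Degenerate inputs are handled explicitly: empty intronic regions emit no
records, zero-variance strata are non-evaluable, all-tied group
comparisons return p = 1 with a warning, samples with no expressed
candidates binarize to all-false with a warning.

## Known limitations

* The permutation DE stand-in is not SAM: it uses a fixed s0 (median
  pooled SD) rather than SAM's tuned percentile, and reports pooled
  permutation p-values rather than SAM's delta-threshold FDR estimate.
  Gene *sets* passed downstream are expected to agree closely; per-gene
  scores are not interchangeable with SAM's.
* Orthologue handling is a plain two-column map file; no remote lookups.
* The pyknon module searches input motif lists; it does not discover
  motifs.
* Family attribution treats any-strand, any-copy overlap as membership;
  no weighting by copy number or overlap length.
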