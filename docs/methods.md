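# Methods

## The analysis

The package implements association mapping from pooled sequencing
(pool-seq) of phenotyped insects, in the setting of pyrethroid resistance
in *Aedes aegypti*: for each of several collections, resistant and
susceptible females are sequenced as replicate DNA pools (two pools of 25
diploid individuals per phenotype class), and allele frequencies are
estimated from per-site nucleotide read counts rather than genotypes.

### Per-SNP test

At each genomic site the replicate libraries are summed within phenotype,
giving a 2 × k contingency table over the k nucleotides with nonzero total
count. The statistic is Pearson's

    χ² = Σᵢⱼ (Oᵢⱼ − Eᵢⱼ)² / Eᵢⱼ,   Eᵢⱼ = rowᵢ·colⱼ / N

with df = k − 1 and the upper-tail p-value of the χ² law. The per-site
score is −log₁₀(p), capped at 320 (the double-precision underflow bound)
so that saturated sites remain finite in downstream averages. Nucleotides
with zero total count are dropped before forming expectations, so no cell
has zero expectation.

An alternative df convention — number of *alternate* (non-reference)
nucleotides minus one — is available behind `df_rule="alternates_minus_1"`.
Taken literally it yields df = 0 at biallelic sites, which admits no test,
so it applies only from k = 3 upward and falls back to df = 1 at k = 2.
The default (observed alleles − 1) is the standard 2 × k contingency df.

Summing replicates before testing treats the comparison as
resistant-versus-susceptible; a separate replicates × alleles χ²
(`replicate_heterogeneity`) quantifies disagreement between pools of the
same phenotype as a diagnostic, but never gates results.

Per-phenotype expected heterozygosity at a site is Hexp = 1 − Σ pᵢ² over
the phenotype's pooled read frequencies; it is bounded by 1 − 1/k and is
undefined (not zero) when a phenotype has no reads.

### Site filters

Sites enter testing only if **every** library reaches the minimum depth
(default 15). The rule is per library, not on the total, mirroring a
per-sample minimum-coverage option in upstream read-count callers; with
four libraries the kept sites necessarily have total depth ≥ 60. Sites
where a single nucleotide carries every read are excluded as monomorphic;
sites with no reads at all are a separate "no-data" class so the two
exclusion reasons are never conflated. Base-quality filtering is treated
as an upstream concern: synthetic counts are post-quality by construction.

### Gene scores and the high-association set

Sites map to every gene whose 1-based inclusive interval (UTRs + exons +
introns) contains them; a site inside two overlapping genes counts for
both, and intergenic sites are counted but discarded. A gene's score is
the mean of its top m site scores with m = max(1, ⌈0.05·n⌉) — a weighted
average that rewards a localized cluster of strongly differentiated SNPs
over uniform mediocrity, since most sites in a gene are expected to carry
no signal. Ties at the m-th value are interchangeable, so the score is
invariant to input order, bounded above by the gene's maximum site score
and below by its mean.

Two criteria gate the high-association set, recorded separately and both
required: (a) at least one of the gene's sites is rejected by
Benjamini–Hochberg FDR control at α = 0.01 applied across all tested site
p-values of the collection, and (b) the gene score reaches the cutoff 4.0
(inclusive). The level at which FDR is controlled is a genuine design
choice: the p-values are site-level objects, so the default applies BH at
the site level before gene-level thresholding; `fdr_level="gene"` (BH on
each gene's minimum p) is available as a sensitivity analysis.

### Cross-collection synthesis

High-association sets from ≥ 2 collections are intersected with full
Venn-region accounting (region counts sum to the union). Named non-coding
genes can be removed from the intersection, with the removal counted. The
"extreme" subset takes, per collection, the nearest-rank 90th percentile
of common-set scores as a threshold and keeps genes *strictly* above it in
every collection; strict exceedance means a degenerate (constant) score
distribution yields an empty extreme set, and a small common set can
legitimately produce no joint member. Membership is invariant to monotone
affine rescaling of any collection's scores. Positional summaries count
common genes per chromosome and per arm (arm boundaries are caller
configuration) and report signed distances from gene midpoints to a focal
locus; the voltage-gated sodium channel interval on chromosome 3 is
provided as the default focal locus. Share-of-cluster figures are
reported as raw ratios; `percent_truncated` truncates (not rounds) for
presentation, leaving the convention explicit.

### Category enrichment

Each functional category of the high-association set is tested against
the background annotation with the upper-tail hypergeometric probability
P(X ≥ k) for population N, category size K, draw size n and observed
count k, evaluated through scipy's stable log-space routines. The
mitochondrial and redox categories are merged before testing by default,
since key redox enzymes localize to mitochondria. Raw p-values are
reported — one test per category, no adjustment — with an optional BH
column off by default. Genes missing a category are assigned UNK and
counted.

## The synthetic generator

The generator emulates the post-alignment read-count tables the study
design would yield: three collections × {resistant, susceptible} × two
replicate pools of 25 diploid females, three chromosomes, genes spanning
their full genomic footprint with non-overlapping intervals, and a
minority of genes (20 of 100 by default) carrying a resistance signal.

Sampling follows the physical process in two stages. In `pooled` mode each
replicate pool first draws 2 × 25 chromosomes binomially from the
phenotype's population frequency; reads are then drawn multinomially from
the realized pool frequency. The read-frequency variance across pools
therefore approaches the finite-pool bound p(1−p)/50 at high depth rather
than vanishing — the dominant noise source in deep pool-seq. `ideal` mode
draws reads directly from the population frequency; it exists because the
read-level χ² assumes independent reads, and only in this mode is the
test nominally calibrated (the null fraction of p < 0.05 sits at ~0.05
for ≥ 10⁴ biallelic sites). In pooled mode the same test is
*anticonservative* — with per-pool depth ≈ 150 the effective χ² inflation
is roughly fourfold — so high-association sets contain non-causal genes
alongside essentially complete causal recovery. This mirrors the
read-level test's behaviour on real pool-seq data and is why the
calibration claim is made only under ideal mode.

Causal genes carry an allele-frequency differential `delta` (default
0.35) at every one of their sites: the primary alternate allele gains
delta in the resistant class at the expense of the reference allele. An
infeasible frequency (baseline + delta outside [0, 1]) is a hard error
naming the site — never a silent clip. Baseline alternate-allele mass is
uniform on [0.05, 0.5]; a configurable fraction of sites (default 2%)
splits it over two alternate alleles to exercise the df rule. Sequencing
error miscalls each read uniformly onto the other three nucleotides
(default 0.001) — the simplest symmetric model, sufficient to exercise
multi-allele handling. Per-library depth is negative binomial
(mean 150, dispersion 8), reproducing the heavy-tailed spread of
exome-capture coverage at reduced scale.

Functional categories use 8 of the field's 13 category codes. Background
rates are uniform over the categories *as tested downstream*: because MIT
and ReDox are merged before testing, those two codes split one group's
share, keeping the merged null categories exchangeable. The planted
enrichment is an exact rate multiplier — a causal gene carries the
planted code (TRP, the transport category) at 5 × its background rate
(5/7 ≈ 0.71), the remaining mass spread over the other codes — with a
hard error if the planted mass would exceed 1. Gene layout, categories
and the causal set derive from the master seed alone, so all collections
of a study share them, while SNP positions, baseline frequencies, pool
draws and read noise are collection-specific. Identical configuration and
seed reproduce byte-identical files.

What the generator does **not** emulate: linkage disequilibrium and
selective sweeps (sites are independent, so physical clustering of
association beyond gene boundaries cannot arise), capture-probe dropout,
alignment and base-quality artifacts, indels, unequal individual
contributions within a pool, and genome-scale site counts. Passing tests
therefore demonstrate the statistical machinery on an idealized genome at
reduced scale, not robustness to those real-data features.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `min_coverage` | 15 reads/library | per-library depth floor for testing |
| `alpha` | 0.01 | BH FDR level across a collection's site p-values |
| `cutoff` | 4.0 | gene-score threshold, inclusive |
| `top_fraction` | 0.05 | fraction of a gene's sites averaged (floor 1 site) |
| `extreme_fraction` | 0.10 | joint top-fraction for the extreme subset |
| `neglog10p_cap` | 320 | keeps underflowed p-values finite in averages |
| `pool_individuals` | 25 (diploid) | pool size per replicate library |
| `replicates_per_phenotype` | 2 | pools per phenotype class |
| `delta` | 0.35 | causal allele-frequency differential between classes |
| `coverage_mean`, `coverage_dispersion` | 150, 8 | negative-binomial depth per library |
| `seq_error` | 0.001 | per-read uniform miscall probability |

## Problem sizes

The default study simulates 100 genes with 10–30 SNPs each (~2,000 sites
per collection, ~6,000 tests per study), sizes at which the full pipeline
runs in seconds while leaving every statistical property measurable: the
null calibration uses ~11,000 biallelic sites, the planted-category check
repeats the full three-collection study over 20 seeds, and the oracle
cross-checks sweep 1,200 random contingency tables and all ~1.2 million
hypergeometric configurations with N ≤ 60.

## Known limitations

- The read-level χ² is valid as a test of read-frequency difference, not
  of population allele-frequency difference, once pool resampling
  dominates; a pool-aware variance correction is out of scope here.
- FDR control is nominal only under ideal-mode sampling; under pooled
  sampling the realized site-level FDR exceeds α.
- The extreme subset uses strict exceedance of nearest-rank thresholds;
  with few common genes or score saturation at the −log₁₀(p) cap it can
  be empty.
- Arm-level summaries require user-supplied centromere positions; none
  are bundled.
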