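# Methods

## Signal model and units

Coverage is represented as per-bp signal density in fixed-size bins
(default 25 bp), with the library size carried separately. Every reported
quantity is therefore on a sequencing-normalized scale:

- **RPM density** — mean per-bp signal × 10⁶ / library size (metagenes,
  eRNA profiles, ranked-signal curves);
- **total RPM** — summed signal × 10⁶ / library size (region scores,
  per-site occupancy);
- **RPKM** — reads × 10⁹ / (library size × length in bp) (gene-level
  occupancy).

Queries not aligned to bin edges use fractional bin overlap, so interval
sums are exact integrals of the piecewise-constant density; the
length-weighted mean of any partition of an interval reproduces the
whole-interval mean to 1e-9. All coordinates are 0-based half-open; GTF
(1-based inclusive) is converted at the I/O boundary only.

## Super-enhancer calling

Constituent peaks with same-chromosome gaps strictly below the stitching
distance are merged; each region is scored by total factor RPM, minus
total control RPM when an input track is given, floored at 0; replicate
factor tracks are averaged. Regions are ranked ascending and both axes
min–max scaled to [0, 1]; the cutoff index maximizes x − y, the point
where a slope-1 tangent touches the convex rank–signal curve, and regions
strictly above the cutoff signal are super-enhancers.

Choices:

- **Stitch distance 12,500 bp** and **gene-assignment window 50 kb** — the
  standard defaults of ranked-signal super-enhancer calling; both
  configurable.
- **TSS exclusion default 0 (off)**: lineage-factor super-enhancers here
  legitimately include promoter-proximal constituents; the flag removes
  peaks fully contained within ±window of a TSS before stitching when
  wanted.
- **Tie-break toward the larger index**: on exactly tied diagonal
  distances (e.g. a perfectly linear curve) the cutoff lands at the top
  rank, flagging *fewer* regions — the conservative call.
- **Degenerate input**: all-equal signals have no elbow and raise an
  error rather than fabricating a cutoff; fewer than 3 regions likewise.
- Gene ↔ region association: a gene is linked to a region if its TSS is
  within the window of the region boundaries or the gene body overlaps
  the region; one super association classes a gene "SE" regardless of
  additional typical associations.

## Metagenes and the elongation ratio

Gene bodies are rescaled to a fixed number of bins (default 100) with
fixed-bp flanks (default 2 kb in 50 bp bins); minus-strand genes are
reversed so bin 0 is always 5′; the profile is the unweighted mean over
genes of per-bin RPM density. Genes shorter than the body bin count in bp
or with flanks leaving the chromosome are dropped and logged; an empty
result is an error. The two-condition elongation curve is
log₂((a+ψ)/(b+ψ)) per bin with a shared pseudocount ψ = 0.1 RPM — small
against promoter signal, large enough to stabilize empty bins. A curve
that increases across the body means polymerase travels further in
condition *a*; the tests summarize this as the Spearman correlation of
body bins against bin index.

## Site and gene classification

A peak's position is its summit when present, else its midpoint. Context
classes use precedence proximal (< 2 kb from any TSS, strand-aware) >
distal intragenic (inside any gene body) > distal intergenic, so classes
partition any peak set. Per-gene co-occupancy is "TSS + intergenic" when
a proximal peak lies within the TSS window *and* a distal intergenic peak
links to the gene — through the enhancer–gene map when the peak falls in
a mapped region, else (by default) through nearest TSS; "TSS only" when
only the former holds.

## Differential occupancy

Per-site signal is total RPM over the site interval in each condition;
log₂fc = log₂((b+ψ)/(a+ψ)) with the shared ψ, so depletion in the
perturbed condition is negative. Sites group as **SE** (inside a called
super-enhancer, or at the TSS of an SE-associated gene), **typical**
(analogously), else **other**; group labels partition the site set and
counts are always reported. Group comparisons run both a two-sample K-S
test and a Mann–Whitney U test (SE vs other, typical vs other by
default), two-sided; no multiple-testing correction is applied to the
planned comparisons (a Benjamini–Hochberg helper can be layered on when
batching across factors). Factor-dependent sites are those at or below a
log₂fc threshold (default −1); feeding them back through a second
factor's changes asks whether losses are coupled.

Statistical tests: K-S D is the supremum ECDF gap over the pooled
support; its p-value is exact for small samples and otherwise uses the
asymptotic Kolmogorov distribution with effective n = n₁n₂/(n₁+n₂).
Mann–Whitney U uses midranks for ties; the p-value is the exact tie-aware
permutation probability when the pooled sample size is ≤ 16 (where the
normal approximation can err by tens of percent), otherwise the normal
approximation with tie-corrected variance and continuity correction. Two
samples with all values identical return U = n₁n₂/2, p = 1. Both tests
are checked against independently coded brute-force oracles and for null
calibration (type-I error at α = 0.05 within [0.03, 0.07] over 1,000
repetitions) in the acceptance suite.

Fold-change gene sets use (a+ψ)/(b+ψ) ≥ threshold (default 2.0,
thresholds ≤ 1 rejected), giving disjoint condition-specific sets.

## Enhancer RNA

Profiles average per-strand RPM density in bins over ±window (default
2 kb, 81 bins so the midpoint has a central bin) around site midpoints in
genomic orientation; the default aggregate is the unnormalized mean, with
a median option. Bidirectionality is min/max of the two strand sums over
the window (0 when both are silent, 1 iff both are equal and non-zero).
Cross-condition specificity is the per-site log₂ ratio of both-strand
total RPM, summarized by the median per site set.

## The synthetic study

The generator emulates the data layer of a two-condition ChIP-seq /
RNA-seq / expression study of a lineage-defining factor:

- **Genome**: 2 chromosomes × 5 Mb. Each chromosome has a regulatory zone
  (all enhancer elements plus half the genes) and an enhancer-free zone
  (the other half of the genes, separated by a 60 kb buffer — wider than
  the gene-assignment window), so a natural population of
  enhancer-independent "other" sites exists. Elements (400 genes of
  2–10 kb, 300 typical peaks of 400 bp, 20 clusters of 5–10 constituents
  within ≤ 10 kb spans) are shuffled and placed left to right with random
  gaps ≥ 3 kb, so nothing overlaps and every enhancer site is intergenic
  by construction.
- **Coverage** is simulated directly as pileup density (no read/alignment
  step): Poisson background (0.01 reads/bp for ChIP, 0.002 for RNA) plus
  deterministic Gaussian pileups (sd 150 bp, approximating
  sonicated-fragment pileups) of the planted areas. Library size is a
  fixed 10⁷ for every track, i.e. depth-matched conditions, so planted
  amplitude ratios survive RPM normalization exactly.
- **Factors**: one shared site geometry; per-site amplitudes are
  lognormal-jittered (σ = 0.25) but shared across conditions, so planted
  depletion ratios are exact. Typical sites carry 100 reads, constituents
  10× that. The first factor is the sequence-specific lineage factor
  (enhancer sites only); all others also bind 200 gene promoters.
  Perturbations divide condition-b amplitudes: everywhere
  (`depletion_all`, e.g. the knocked-out factor itself) or at
  super-enhancer constituents only (`depletion_se`, default 4-fold for
  the elongation machinery in the knockout scenario, with Brd4 and RelA
  untouched).
- **Pol II**: promoter Gaussian (area 20,000 reads) at each TSS plus a
  gene-body density of 10 reads/bp × eff^x, where x is the fraction
  travelled from the TSS and eff the per-condition elongation efficiency
  (0.9/0.9 baseline, 0.9/0.3 in the elongation-contrast scenario); past
  the TES the end density decays exponentially (length constant 500 bp).
  Under this survival model the cross-condition log₂ ratio grows linearly
  across the body, the signature the metagene analysis detects.
- **RNA**: strand-split; sense gene-body density proportional to the
  expression table (0.01 reads/bp per expression unit); bidirectional
  eRNA at every intergenic enhancer midpoint as equal-area Gaussians
  offset ±150 bp on the two strands (area 30 reads at typical sites, 5×
  at super-enhancer constituents — deliberately sub-linear in the 10×
  factor amplitude, as enhancer transcription saturates; the
  eRNA-contrast scenario collapses the SE boost 5-fold in condition b).
- **Expression**: per-gene lognormal baseline (median 100, σ_log = 1)
  shared across conditions, ×√8 / ÷√8 for the 50+50 planted lineage
  genes (8-fold), with per-condition lognormal noise of 0.5 log₂ units.
- **Randomness**: one RNG stream per output, seeded from (seed,
  CRC32(name)), so adding a track never perturbs existing ones; the same
  seed yields byte-identical files.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level artifacts (duplicates,
GC and mappability bias), fragment-length estimation, peak-calling error
(peaks are exact), overlapping or nested genes, splicing and poly-A
status (the "total RNA" track simply carries the planted eRNA),
correlation between enhancer assignment and expression beyond the
planted lineage labels, and biological replicate variability (replicate
handling is exercised only as track averaging).

## Pipeline and reproducibility

The CLI layers thinly over the library: flags > config file > defaults;
every command writes a manifest with the config echo, tool version, seed
and SHA-256 checksums of inputs/outputs, and identical invocations are
byte-identical. `scripts/acceptance.py` recomputes all headline
quantities from fresh simulations at the scales noted in its output
(full-size baseline/contrast studies; 1,000 random vectors for the
cutoff oracle; 500 small pairs for the test oracles; 1,000 null
repetitions for calibration; 100 seeded repetitions for the
knockout-contrast specificity; a reduced 2 × 0.5 Mb study for the
double-run determinism check).

## Known limitations

- Gene-body pol II fill is bin-aligned, so a gene's realized signal can
  exceed the nominal density × length by up to one bin per edge;
  analyses compare like with like, but absolute totals carry this bias.
- `occupancy_changes` quantifies every site as total RPM over its
  interval; per-gene RPKM quantification is available separately
  (`gene_rpkm`) but not switched automatically by site class.
- The enhancer–gene map is proximity-based (window/overlap); no contact
  or correlation evidence is modeled.
- The exact Mann–Whitney route enumerates combinations and is only used
  for pooled n ≤ 16; forcing `method="exact"` on large samples is slow.
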