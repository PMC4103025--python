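# Methods

## Coordinates and data model

All coordinates are 0-based half-open (BED convention). A *tag* is one
aligned read reduced to its 5′ position and strand; the 5′ position of a
minus-strand BED record `[start, end)` is `end − 1`. Gene models aggregate
BED records by name; the canonical TSS is the 5′-most transcript start on
the gene's strand (minimum start for `+`, maximum 5′ position for `−`).
"Gene body" means the full transcribed extent `tx_start..tx_end`; no
CDS-level annotation is used, so "genic" in context labels is a
transcript-body dialect, not a coding-exon one.

## Genome partition

Each chromosome is partitioned by priority into TSS-proximal windows
(TSS ± `flank`), gene bodies outside those windows, and the intergenic
remainder. The default `flank` is **2,000 bp**: wide enough that a broad
repressive domain touching the promoter flags the gene, narrow enough that
state calls stay TSS-local. The metagene plots use a wider ±3 kb view, but
that is a display window, not a call window; both are configurable and
deliberately controlled by separate parameters.

## Coverage and normalization

Tags are extended to a nominal fragment length of **200 bp** in their 3′
direction (the usual single-end ChIP-seq treatment) and binned at
**50 bp**; a bin counts every fragment overlapping it. Window intensities
count extended-fragment overlap with `[tss − flank, tss + flank)` — not 5′
containment — which matches figure-style smoothed intensity. The
normalization unit is tags per 10 million library tags. Metagene profiles
orient offsets 5′→3′ along each gene before averaging; the minus-strand
window arithmetic is mirror-exact (the bin at offset *o* covers the bases
*o*..*o*+50 downstream of the TSS in gene orientation on either strand).

## Domain calling

Sliding windows (per-mark defaults: 200/200 bp window/step for the sharp
H3K4me3, 1,000/500 bp for the broad H3K27me3 and H3K36me3) are tested with
an upper-tail Poisson p-value `P(X ≥ k_chip | λ)` where

λ = max( (input_window + 0.5) · r, (input_10kb + 0.5) · r · w/10kb, gw ),

`r` the chip/input library ratio, `w` the window width and `gw` the
genome-wide ChIP expectation for one window. Taking the maximum of a local
and a global background is the standard guard against local biases; the
0.5 pseudocount keeps λ positive in empty input regions. Benjamini–Hochberg
FDR is applied across all windows (q < 0.05 by default); significant
windows merge when closer than `max_gap` (window-sized by default), and a
domain's score is −log10 of its best window q. Domain context is
`intergenic` only with *zero* overlap of any TSS window or gene body;
otherwise the larger of the TSS-window and genic overlaps decides, ties
going to `tss_proximal`. Note that a window-granular caller reports domain
widths quantized to the window/step grid, so called widths overestimate
sub-kilobase features by up to about one window on each side.

## Four-state TSS classification

A gene has a mark iff any called domain of that mark overlaps its TSS
window. The two boolean flags map deterministically to K4_ONLY, K27_ONLY,
BIVALENT or NONE; H3K36me3 is deliberately not part of the state label and
is reported as gene-body coverage instead. Cross-condition comparison
cross-tabulates states over the genes present in both call sets (genes on
chromosomes missing from one condition are reported separately, not
coerced to NONE); retention is the diagonal over the row sum. Bivalency
here means co-occurrence of both marks in the same TSS window — no claim
about the same nucleosome carrying both marks is made or testable from
single-mark ChIP data.

## Cross-age intensity comparison

Per-gene fold changes use a pseudo-intensity of 0.5 on both sides; the
global fold change is the ratio of mean TSS-window intensities with no
pseudocount (robust to zero-intensity genes; both are reported).

Scaling matters here. Scaling each track by its own library size (tags per
10 M) is correct within one sample but *cancels any genome-wide change of
a mark*: if every H3K27me3 region gains 4×, the H3K27me3 library grows in
proportion and the normalized profile is unchanged — algebraically, the
measured fold is `(window_old/total_old)/(window_young/total_young)`, which
tends to 1 whenever the windows dominate the library. The package therefore
scales each age's ChIP counts by its **matched input library** for
young-vs-old comparisons (the pipeline default when inputs are present;
`normalization="library"` remains available for within-sample use). Input
libraries are insensitive to the mark's abundance, so this puts both ages
on a common per-cell-equivalent scale — the same reasoning that motivates
spike-in calibration in quantitative ChIP-seq. This is an explicit modeling
commitment: it assumes IP yield tracks epitope abundance between the two
samples, and the synthetic generator simulates exactly that world (library
size is an outcome of the rates, not rescaled to a fixed depth).

## Expression integration

The poised-state comparison is a two-sided Wilcoxon rank-sum of bivalent
genes against all genes. Condition signatures use
`score(g) = expr[g, target] − max_other expr[g, other]` with defaults
min_score = 1 (2-fold in log2) and min_level = 6 (detection threshold);
with a positive min_score a gene cannot be specific to two conditions.
">40 % down-regulated" is evaluated on the linear scale:
`2^(old − young) < 0.6`. Gene-set enrichment is the upper-tail
hypergeometric `P(X ≥ k)` with BH correction across sets and a minimum
effective set size of 3.

## The synthetic generator

The generator is the package's test bed: it emulates the *shape* of TSS
chromatin data, not any particular genome.

* **Layout** — genes occupy evenly spaced 10 kb slots, TSS at the slot
  centre, body length U[4,000, 7,000] bp extending 3′ along a random
  strand. This guarantees no gene's enrichment geometry reaches a
  neighbour's TSS window, so the ground-truth state of each gene is
  recoverable in principle; real genomes violate this (overlapping genes,
  shared promoters), and recovery numbers on synthetic data are accordingly
  upper bounds.
* **Geometry** — H3K4me3: TSS ± 500 bp, strong (default 2.0 tags/bp above
  background); H3K27me3: TSS ± 5,000 bp, broad and weaker; H3K36me3:
  uniform over the bodies of genes expressed above the median (no exon
  structure). Bivalent genes carry both TSS rates.
* **Tags** — a Poisson point process: uniform background everywhere
  (rate = `depth` / genome length; `depth` is the expected *input* library,
  default 2×10⁶ on the 10 Mb default genome) plus each region's rate;
  strands uniform; 36 bp single-end reads whose only downstream-relevant
  features are 5′ position and strand. Library sizes follow from the rates
  (see above); passing an explicit `depth` to `simulate_chip` instead
  rescales all rates to a fixed expected total.
* **Expression** — log2 intensities drawn per state (means 8 / 3 / 2.5 / 2
  for K4-only / bivalent / K27-only / none, sd 1), plus N(0, 0.05)
  technical noise per condition; histone-flagged genes are forced to be
  robustly expressed (N(9, 0.5)).
* **Aging transform** — multiplies every H3K27me3 rate by 4, switches the
  histone-flagged genes to BIVALENT at the aged H3K27me3 rate, plants
  disjoint novel intergenic domains (widths U[500, 1,000] bp, rate 2× the
  aged gene rate so the narrow peaks clear the signal-inflated genome-wide
  background) at least 2.5 kb from any gene body, TSS window or H3K27me3
  span, and reduces histone-gene expression by the configured factor
  (default 0.5, i.e. one log2 unit). The young truth is never mutated.
  The dense default layout (1,000 genes filling every slot) has no
  enrichment-free intergenic space, so the aging transform requires a
  sparser layout and raises a clear error otherwise.

### Study configurations

Two configurations are used by the validation suite, chosen by design-time
power analysis rather than tuned afterwards:

* **Default study** (state recovery): 10 Mb genome in 5 chromosomes, 1,000
  genes, input depth 2×10⁶ (0.2 tags/bp background), state proportions
  0.40/0.25/0.20/0.15 (K4/bivalent/K27/none), 20 histone-flagged genes.
  Every mark's window-level signal-to-background exceeds z ≈ 13, so the
  expected state accuracy is essentially 100 %.
* **Aging study** (fold-change recovery): same genome with 500 genes (every
  other slot empty, leaving room for intergenic domains), input depth 5×10⁵
  (0.05 tags/bp) and H3K27me3 rate 1.0 tags/bp. The measured global fold is
  structurally below the true multiplier because the window background
  common to both ages dilutes it: with signal-to-background ≈ 20 in the TSS
  windows and the gained histone genes adding to the old numerator, the
  predicted global fold is ≈ 3.9 for a true 4×, comfortably inside a ±15 %
  recovery band. At the default study's higher background the same
  estimator would read ≈ 2.7 — measurably, and correctly, attenuated —
  which is why the aging comparison gets its own documented conditions.

### What passing tests do and do not show

The generator has uniform mappability, no GC bias, no duplicate-read
structure, no replicates, non-overlapping genes and exactly one TSS per
gene. Recovery results therefore validate the *computation* (the caller,
the classifier, the estimators) under the stated noise model; they do not
certify performance on real libraries, where annotation ambiguity and
coverage biases dominate the error budget.

## Numerical choices

* Poisson and hypergeometric tails come from scipy; BH from statsmodels;
  both are cross-checked in the test suite against independent
  brute-force summation/enumeration oracles to 1e−12.
* BH ties break by stable sort order; merged-domain scores use the best
  window; −log10(q) is capped at 300 to avoid infinities.
* Degenerate inputs fail loudly: empty libraries cannot be normalized,
  empty gene lists cannot yield TSS tables, disjoint call sets cannot be
  cross-tabulated; empty domain sets produce n = 0 / NaN summaries rather
  than errors.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived streams use fixed sub-stream ids, so
  every artifact is a pure function of (config, seed).

## Known limitations

Single-end, fixed fragment length; no BigWig/BAM I/O (BED only); no
replicate-aware calling (no IDR); window-granular domain boundaries; the
four-state model ignores mark intensity below/above the presence
threshold; the input-scaled cross-age comparison inherits the
IP-yield-tracks-abundance assumption and will understate changes if IP
saturates.
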