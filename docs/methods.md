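# Methods

## Coordinate and sequence conventions

All genomic coordinates are 0-based half-open (BED convention) throughout;
the merge and proximity operations copy bedtools semantics exactly, so no
conversion ambiguity arises anywhere in the pipeline. All sequence
comparison happens in the DNA alphabet — U is converted to T on input —
while composition reports display RNA letters (U), matching how piRNA base
preferences are conventionally quoted. Scaffold names are the FASTA header
token before the first whitespace.

## Prefiltering

The read-level cascade is length → miRNA → tRNA → (repeat mask, on mapped
positions) → low abundance, with per-stage accounting that must balance
exactly (unique sequences and total reads). Choices the underlying protocol
leaves open, and how they are resolved here:

- A "hit" on a miRNA hairpin or tRNA is an **exact substring occurrence on
  either strand**. This is the strictest reproducible reading; a
  Hamming-distance ≤ k option exists but is off by default.
- Repeat-mask exclusion removes alignments overlapping masked intervals of
  classes tRNA, rRNA, Simple_repeat, Low_complexity by **any overlap
  (≥ 1 bp)**; TE-derived classes (LTR, LINE, SINE, DNA, RC) are retained,
  and an unrecognized class string is retained with a warning — the
  conservative direction, since dropping reads on an unknown label risks
  discarding genuine piRNAs. The mask is applied to mapped positions (the
  mask file is genome-anchored); applying it to read sequences instead would
  require realigning mask intervals to reads and is not implemented.
- The low-abundance floor (count ≥ 10) applies to oxidized samples before
  reference construction and is optional elsewhere.
- Adapter trimming and quality clipping are out of scope; inputs are assumed
  to be clean reads.

Each filter is idempotent, and the cascade applied twice equals the cascade
applied once — asserted by tests.

## Exact mapping

Seed-and-verify over a hashed k-mer index with k = 25, the minimum read
length: a single seed lookup followed by full-read string comparison is
guaranteed exact for 25–32 nt reads. All occurrences on both strands are
reported; there is no placement cap by default (`max_hits` exposes one).
Reads containing ambiguous bases never match — exact matching has no
mismatch policy to place them under. Palindromic placements are reported
once per strand. Equivalence with a naive substring scan is asserted on
random genomes in the test suite.

## Cluster reference construction

Mapped positions are merged transitively whenever the gap to the next
position is ≤ 1000 bp (book-ended and overlapping intervals always merge).
Merging is **strand-agnostic by default**: plain `mergeBed -d 1000` ignores
strand, and a `stranded` flag preserves the alternative reading. Merging is
idempotent and monotone in the distance (larger d never yields more
clusters).

Counting is **full count per placement**: a multi-mapping read contributes
its whole count at every placement (all-matches mapping defines no
fractional rule); `count_mode="fractional"` divides by the number of
placements instead. The two reference filters are a conjunction, so their
order is irrelevant (asserted on an exhaustive grid):

- count floor: drop when oxidized < 10 **and** testis < 10;
- oxidation ratio: drop when oxidized/testis < 0.1. Edge rulings: testis = 0
  with oxidized > 0 gives ratio +∞ (passes); oxidized = 0 with testis > 0
  gives ratio 0 (fails) — consistent with the filter's purpose of removing
  leftovers of abundant non-piRNA RNAs, which are exactly the sequences
  depleted by oxidation. Raw counts are used (no normalization is defined at
  this stage); a counts-per-million option exists for unequal library sizes.

Gene proximity uses closest-feature semantics with distance 0 on overlap,
ties broken to the lower-coordinate gene, and a 10 kb proximity flag.

## Classification

With the expression floor e = 10, testis threshold t = 50, and the somatic
sum threshold defaulting to the number of somatic samples n:

- testis-only ⇔ sum(somatic) < n AND testis > t (strict >);
- else soma-and-testis ⇔ testis ≥ e AND max(somatic) ≥ e (≥, as printed);
- else other.

Evaluating testis-only first keeps the two sets disjoint in the rare grid
cells where both inequalities hold. Ovary is germline and excluded from the
somatic sum by default (`somatic_roles` is configurable). Classification is
invariant to somatic column order.

## Base statistics

Composition and pathway ratios are **read-count weighted** by default
(distributions over sequenced piRNAs); unique-sequence weighting is exposed
because either reading is defensible. The primary/secondary ratio counts
1U-not-10X reads over not-1U-10X reads (X = A, or G for guanine-biased
samples); reads satisfying both or neither are excluded, and a zero
denominator is flagged rather than silently dropped. Under uniform random
bases both categories have probability 3/16, so the ratio converges to 1 —
the calibration used in tests. The chi-square bias test defaults to a
uniform 1/4 background (df = 3); a genome-composition background can be
supplied. Totals under 20 warn about asymptotics.

## TE annotation

The enrichment unit is the **distinct TE**: a TE hit by many clusters counts
once. Per class, the fraction among hit TEs is compared with the fraction in
the full library by a two-sample equality-of-proportions chi-square with
continuity correction (identical to the Yates-corrected 2×2 test), flagged
at p < 0.1 / 0.05 / 0.01; raw p-values are reported and multiple-testing
correction is left to the caller. The internal matcher (exact 15-mer seed,
bidirectional ungapped extension, stop when the accumulated mismatch
fraction exceeds 1 − min_identity, minimum alignment length 50) is a
deliberately simple synthetic-scale matcher, not a replacement for a proper
local aligner; production runs should supply precomputed 12-column tabular
alignments via the external engine, to which the identity threshold
(> 90 %) is applied. A QC flag reports whether any cluster sequence
contains a known miRNA hairpin.

## Differential expression

The DE stage is a documented lightweight substitute for a full
shrinkage-GLM stack:

- **Size factors**: median-of-ratios over clusters with a nonzero geometric
  mean, rescaled to geometric mean 1. This estimator assumes most clusters
  are unchanged between samples; when a large fraction of features shifts,
  the median absorbs part of the fold change (visible in tests as fold
  compression when half the features are planted DE).
- **Dispersion**: per-cluster method of moments pooled across groups, shrunk
  toward a trended fit α(µ) = a₁ + a₀/µ with weight df/(df + 10); with no
  replication the trend (or a prior of 0.1) is used alone.
- **Test**: conditional exact test on the group sums — a sum of n iid NB(r, p)
  is NB(nr, p), and conditioning on the total gives a two-sided p-value by
  summing all splits no more likely than the observed one. When the
  estimated variance does not exceed the mean the Poisson limit applies and
  the conditional law is binomial. Calibration (type-I error ≤ 0.075 at
  α = 0.05 over 2000 null NB clusters) and power (≥ 0.8 on 8-fold shifts at
  mean 200, dispersion 0.2, 3 vs 3) are asserted in tests.
- **Filters**: expressed = one group mean raw count > 10 and |log2FC| > 2;
  DE = |log2FC| > 2 (fold > 4) and p < 0.05. Fold changes use normalized
  group means with a 0.5 pseudocount for stability at zero counts. Raw group
  means feed the expression filter (independent-filtering convention).
- Externally computed per-cluster p-values can be substituted
  (`--external-pvalues`) to reproduce a third-party DE stack exactly while
  keeping the fold-change and filter logic.

log2FC is antisymmetric under group exchange, and rescaling all counts by a
common constant leaves results unchanged (asserted).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
defaults chosen once as the study conditions:

- 4 scaffolds × 50 kb; 20 planted clusters of 1.2–2.4 kb spaced 5 kb apart
  (> merge distance, so ground truth is unambiguous); 40 % of clusters embed
  a TE copy diverged 6 % from a 10-entry classed library (above the 90 %
  identity threshold, below obvious duplication).
- Each cluster hosts 60 germline piRNA species (plus 40 somatic species in
  shared clusters), placed stratified across the cluster so that coverage
  stays dense after low-abundance filtering, with lognormal(0, 1) abundances.
  The outermost germline species are floored at the lognormal median so the
  planted span stays recoverable after the count-≥10 prefilter — otherwise a
  weak boundary species makes the recorded truth unrecoverable by
  construction. Species bias positions are kept collision-free (overlapping
  species would otherwise overwrite each other's planted bases and dilute
  the configured bias).
- Read lengths 25–32 nt with mode 28. Germline species realize P(1U) = 0.77
  and P(10A) = 0.491; somatic species realize a guanine bias (P(1G) = 0.5,
  P(10G) = 0.4). Biases are planted in the genome itself, so simulated reads
  always map exactly.
- Contaminants per non-oxidized sample: 5 % miRNA-hairpin windows, 3 % tRNA
  windows, 7 % random genomic degradation fragments (placed > 1 kb from
  clusters so they can never bridge into one), with lognormal(0, 0.5)
  abundances — mild skew, so no single fragment can mimic an
  oxidation-resistant locus and plant a spurious cluster. Oxidized samples
  retain 2 % of the non-piRNA mass. Optional "misc" loci (abundant,
  unmethylated) exercise the oxidation-ratio filter: they form preliminary
  clusters that the final filter must remove.
- Six default samples: oxidized testis, testis, two benign controls, two
  tumors, 10⁵ reads each; 8 of 20 clusters are testis-only; 3 shared
  clusters are planted 4.5-fold up in tumors. Per-sample cluster expression
  carries lognormal noise with σ = 0.03.
- All randomness flows from one seed through named child generators
  (SHA-256-tagged SeedSequence spawns), so any sample is reproducible in
  isolation and across processes.

**What the generator does not emulate, and what that implies.** There are no
sequencing errors, no adapters, no quality scores, and replicate variability
is near-technical (σ = 0.03). The last point is a design constraint, not an
oversight: the planted 4.5-fold change sits only 12.5 % above the 4-fold
detection threshold, and with two samples per group the standard error of
log2FC is ≈ 1.6 σ, so planted changes are reliably identifiable only when
σ ≲ 0.03. Real biological replicates commonly vary several-fold more; with
realistic dispersion, folds this close to the threshold would need more
replicates to detect. Similarly, only a small minority of clusters is
planted DE, because median-of-ratios normalization loses its anchor when a
large fraction of features changes. Passing recovery tests therefore
demonstrate correctness of the machinery under its stated assumptions, not
sensitivity under field conditions.

## Problem sizes

Tests and the acceptance script run at deliberately modest scale — 50 kb
oracle genomes with 500 reads, 200 kb simulated genomes at 10⁵ reads per
sample, 1000 random merge instances, 2000-cluster null calibrations — sizes
at which the brute-force oracles remain exact and the whole suite completes
in well under a minute. The pipeline itself is linear in reads and genome
size apart from the k-mer index (one posting per genomic position).

## Known limitations

- The internal TE matcher is ungapped; indel-diverged TE copies require the
  external alignment route.
- The exact NB test conditions on rounded normalized sums; with wildly
  unequal library sizes the rounding is a coarser approximation.
- The classifier follows the printed inequalities exactly; the strict
  testis > 50 boundary means a cluster at exactly 50 testis reads with
  silent soma is labeled "other".
- No multiple-testing correction is applied anywhere p-values are reported
  (raw p-values are the convention being reproduced); callers can correct
  downstream.
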