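# Methods

## The measurement model

A radiation-hybrid line is scored at each marker as retained, deleted or
missing.  The working model is haploid: each line carries one copy of the
target chromosome, radiation breaks it, and lost fragments are scored as
deletions.  For a pair of loci the chain is Markov: with probability 1−θ
the two loci share a single retention event (probability r), with
probability θ they are retained independently, giving

    P(1,1) = (1−θ) r + θ r²
    P(1,0) = P(0,1) = θ r (1−r)
    P(0,0) = (1−θ)(1−r) + θ (1−r)²

θ = 0 is complete linkage, θ = 1 independence.  r is pooled per pair
(average retention over the two columns among pairwise-complete lines),
the simplest choice consistent with the equal-retention haploid likelihood;
missing calls are excluded pairwise everywhere.  Lines retaining or lacking
the whole chromosome stay in the denominator — they are part of the panel
screened — though a flag can exclude them.

The per-pair likelihood in θ has a closed-form interior maximum (the score
equation is the quadratic `θ² r(1−r) n − θ s + b = 0` with n the pair count,
b the discordant count and `s = a(1−r) + c r + b`); the LOD is the base-10
likelihood ratio at that MLE against θ = 1.  The reported point estimate
`theta_hat` is the moment estimator `D / (2 r (1−r))` (D the discordance
fraction), which coincides with the MLE for symmetric retention.  When the
pooled retention is 0 or 1 the pair carries no linkage information and is
flagged degenerate (LOD 0).

Distances are raw discordance: one centiRay is one state difference between
adjacent loci per 100 lines.  This deliberately is **not** the Cox-style
`−100·ln(1−θ)` transform: the map unit is defined directly on the observed
difference rate, and an optional flag exposes the transform for comparison.
Consequence: pairwise distance saturates — beyond roughly `2 λ μ` worth of
separation (about 10 cR under study conditions) all pairs look equally far
apart, which shapes the ordering strategy below.

## Framework map construction

1. **Co-segregation collapse.**  Markers with identical call vectors map
   as one locus.  By default the missing pattern is part of the identity
   (exact match); the wildcard variant lets a marker join a group whose
   consensus it matches on all mutually scored lines.  With realistic
   missingness (~2.5% of calls) exact matching splits most groups — a
   540-marker study panel collapses to ~530 "loci" exact vs ~245 wildcard —
   so the run layer defaults to wildcard grouping while the library default
   stays exact.
2. **Anchor scaffold.**  Because pairwise linkage saturates, the
   chromosome-scale arrangement is not identifiable from the likelihood
   alone at 92 lines; the information that fixes it is cytogenetic: anchor
   markers have known deletion bins, and the bin order along the chromosome
   is known.  When bin metadata is available the anchors therefore form a
   fixed skeleton: bins in cytogenetic order, anchors within a bin ordered
   by the multipoint likelihood (exhaustively for ≤9, insertion+polish
   above), and each bin chain's orientation chosen by dynamic programming
   over the junction likelihoods.  Without anchors the order is seeded from
   the highest-LOD pair instead.
3. **LOD-gated insertion.**  Unplaced loci are evaluated at every slot of
   the current order under the multipoint objective (the sum of adjacent
   maximised pair log-likelihoods — a travelling-salesman path criterion).
   A locus's placement LOD is the log-10 gap between its best and
   second-best slot; the locus with the largest placement LOD is inserted
   while it clears the current threshold of the decreasing schedule
   (default 10, 8, 6, 3).  Loci that never qualify are attached at their
   best slot and flagged non-framework.
4. **Refinement.**  A window-3 ripple pass (all permutations of every three
   consecutive loci) runs to a fixpoint, followed by a deterministic
   2-opt (segment reversal) and Or-opt (1–3-locus segment relocation)
   polish; both accept only strict improvements and, in scaffold mode,
   reject any move that would reorder the anchors.  The polish matters:
   greedy insertion alone was measured to finish >100 natural-log units
   below the true order's likelihood on weak study-size panels.  Maps of at
   most 9 loci skip all of this and are solved by exhaustive enumeration.
5. **Positions and orientation.**  Locus positions are cumulative adjacent
   raw-discordance distances; the map is oriented so anchor bins run from
   the short-arm telomere to the long-arm telomere, falling back to a
   lexicographic tie-break.  All internal ties break on marker ids, so a
   build is fully deterministic.

**Bin assignment** extrapolates anchors to all loci: between consecutive
bins the boundary is the cut on the cR axis that misclassifies the fewest
anchors (the midpoint between the adjacent anchors of the two bins when
they separate cleanly); interleaved anchors are logged and resolved by the
same majority rule.  Each locus inherits the bin of its interval, and a
bin's map span is the distance between its boundaries.

## Deletion calling and sizing

A deletion is a maximal run of deleted loci in map order, bounded by
retained loci or the map ends; missing loci bridge a run without extending
it (a failed assay should not split one physical deletion in two).  Two cR
spans bound each call — inner (first to last deleted locus) and outer
(between the flanking retained loci) — and the reported size is their
midpoint, unbiased when the true breakpoint is uniform within the flanking
interval; both bounds are always reported.  Mb sizes partition the span by
bin boundaries and apply each bin's Mb cR⁻¹ ratio.  Terminal runs are valid
deletions; lines whose single run exceeds a whole arm are classed
SUPRA_ARM_LOSS (translocation remnants) and, like whole-chromosome losses
and intact lines, excluded from deletion statistics.  Line classes follow
retention: exactly 1.0 → INTACT, below 0.020 → WHOLE_LOSS.

## Per-bin statistics and table conventions

For a bin of size S Mb with spans L_cR and L_cM: saturation S/markers,
resolution S/L_cR and S/L_cM, BR frequency (L_cR/2)/S (a deletion requires
a proximal and a distal break, so half the cR count measures break/repair
events), CO frequency L_cM/S, and the cR/cM ratio.  Chromosome-wide values
are totals-based (ΣMb over Σmap length), not means of bin values.
Uniformity is the maximum fold-deviation of a bin metric from the
chromosome average.  Display rounding is half-up to one decimal (two for
ratios ≥10), with raw values retained, because published per-bin tables are
printed at that precision while having been computed from unrounded
intermediates — comparisons against printed cells must therefore allow the
print's input rounding (the acceptance tests propagate ±half-ULP input
intervals).

## Correlation layer

Pearson product-moment r with a two-tailed t test at N−2 degrees of
freedom, N the number of deletion bins entering a comparison; bins missing
either variable drop pairwise (a bin without genetic-map coverage
contributes nothing to CO comparisons).  No multiple-testing correction is
applied across the suite.  Centromere distance is a convention, not a
measurement: arm length × the bin's fractional midpoint, with a flag to
report the bare fraction instead; both are exposed because the underlying
metric of published centromere-distance correlations is unspecified.

The deletion-frequency uniformity check is deliberately not a naive
chi-square on deleted-cell counts: markers within a bin share deletions and
a deletion can straddle a bin border, so marker-level counts are
over-dispersed and bin means correlated (a naive chi-square rejected a true
null ~14% of the time at nominal 5% in simulation).  The packaged test uses
the Hotelling contrast statistic on per-line, per-bin deleted fractions
(lines are the independent unit) calibrated by a seeded centred bootstrap
over lines.  It is conservative under the null at these sample sizes and
reliably rejects gross non-uniformity (in simulation, a 15-percentage-point
frequency shift in three bins is always detected with 62 informative
lines); it is not sharp at the 5% level.

## Synthetic panels

The generator implements the chromatin-openness hypothesis as ground truth:
one latent per-bin factor ω drives both somatic break/repair and meiotic
crossing-over.  Deletions live in openness-scaled coordinates
`v(x) = ∫ ω dx` (one v-unit = one Mb of fully open chromatin): per
informative line they start at rate λ per v-unit (uniformly within each
bin) and extend toward the centromere until an Exponential(μ) amount of
openness mass is consumed, truncated at the centromere.  Within a bin this
reproduces the intuitive parameterisation — deletion count
K_b ~ Poisson(λ ω_b S_b), local length scale μ/ω_b — while making the
per-marker deletion probability exactly `1 − e^(−λμ)` everywhere, i.e. the
deletion *frequency* is flat across the chromosome even though deletion
number and size are not.  Each telomere additionally seeds Poisson(λμ)
terminal deletions (the stationary mass entering from the chromosome end):
physically these are the terminal-deficiency chromosomes cytogenetic stocks
are made of, and statistically they prevent the marker deletion probability
from sagging at the tips.  The adjacent-pair discordance then has the
closed form (verified by Monte Carlo at 5000 lines in the tests)

    m1 = λμ(1 − e^(−δ/μ)),  m2 = λμ e^(−δ/μ)
    P(discordant) = 2 (1 − e^(−m1)) e^(−m1) e^(−m2)

for v-separation δ, first order `2λμ(1 − e^(−d ω_b/μ))` at physical spacing
d in bin b.

Defaults are the study conditions: 92 lines in a 13 : 9 : 8 : 62 mix of
intact / whole-chromosome-loss / supra-arm-loss / informative lines; 11
bins with the published physical sizes (891 Mb total) and marker counts
(540 markers); ω_b proportional to the published per-bin break/repair
activity, normalised to a size-weighted mean of 1 (~26-fold range);
λ = 0.0034 initiations · Mb⁻¹ · ω⁻¹ and μ = 25 Mb·ω, set so that replicate
means reproduce ≈2.8 detected deletions per informative line and a
≈26 Mb mean called size; ρ = 0.2009 cM · Mb⁻¹ · ω⁻¹ so the simulated
genetic map totals ≈179 cM, with Poisson counting noise over a notional F2
of 300; per-read assay error ε = 0.01 scored in duplicate (discordant
duplicate reads become missing — mimicking duplicate genotyping — so calls
flip only with probability ε², and ~2% of calls go missing), plus a 0.5%
base missing rate.  Supra-arm lines lose one whole arm plus a uniform
extension into the other.  Genetic spans use cM_b = ρ ω_b S_b.

What the generator does **not** emulate: real marker ascertainment (the
published panel was pre-selected on 84 markers, inflating within-contig
resolution), genotyping error structure beyond independent per-read flips,
translocation breakpoint biology behind supra-arm lines, interference or
dose-response, and any deviation of true deletion lengths from the
exponential family.  Passing tests therefore demonstrate that the pipeline
recovers the structure this model encodes, not that real chromatin behaves
exponentially.

## Problem sizes in the test suite

Oracle-equivalence checks run 25 instances of ≤8 loci × 200 lines against
exhaustive enumeration.  Order-recovery and calibration checks run 50
study-size replicates (92 lines × 540 markers).  Hypothesis-recovery checks
run 50 + 50 replicates of a 10-bin chromosome with a ten-fold openness
range (and a constant-openness null), 12 markers per bin, anchor fraction
0.4, and a notional F2 of 2000 for the genetic map — sizes at which the
test has measured power ≥90% while the null stays at its nominal level.
Monte-Carlo validations of the discordance closed form use 5000-line
panels.

## Known limitations

- **Global order identifiability.**  At 92 lines and ~2 cR adjacent locus
  spacing, adjacent discordance counts differ from their neighbours by
  about their own binomial noise; the maximum-likelihood order then differs
  from the truth in local arrangements (the polished builder's likelihood
  meets or exceeds the true order's, yet marker-level Kendall τ against the
  truth plateaus around 0.75–0.95).  Perfect order recovery at this design
  would need adjacent discordance several-fold higher or far more lines;
  the anchor scaffold supplies the chromosome-scale arrangement but cannot
  resolve sub-bin noise.  Published maps built from panels of this size
  share this property even if it is not directly observable.
- The uniformity test is conservative (see above).
- Printed-table comparisons are limited by the table's own rounding; cells
  derived from small genetic spans (≤1.6 cM) are only reproducible as
  intervals.
- The Mb sizing of deletions inherits any error in the per-bin physical
  sizes, which are cytogenetic estimates, and the midpoint span convention
  is unbiased only for breakpoints uniform within their flanking interval.
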