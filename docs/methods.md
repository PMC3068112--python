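# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the validation suite does and does not establish.

## Study design emulated by the generator

`budqtl.simulate` reproduces the design of a two-family comparative QTL
study in a clonally propagated conifer:

* two unrelated full-sib crosses (defaults 260 and 500 genotyped progeny)
  segregating for subsets of one species map — 12 linkage groups of 175 cM
  (2,100 cM total), with maternal-testcross, paternal-testcross and
  fully-informative anchor markers (default mix 0.35/0.35/0.30, at least
  two anchors per group so maps stay mergeable);
* six ramets per progeny, one in each of three outdoor (VES) and three
  controlled-photoperiod indoor (AAFC) blocks, followed over two or more
  years;
* bud flush scored 0–6 about every 2 days in spring, bud set scored 0–5
  weekly in late summer, annual height measured once per season.

**Meiosis** is a Markov chain over adjacent marker intervals: each interval
recombines with probability equal to the inverse Kosambi transform of its
length, independently across intervals.  This matches the map function the
mapping side assumes, without an explicit crossover-interference model;
two-locus recombination fractions compose as
`r = ½(1 − Π(1 − 2rᵢ))` across intervals.  Planted QTLs ride on the same
gametes as hidden loci, so marker–QTL linkage is exact.

**Phenology** follows a latent-timing threshold model.  Each ramet-year
draws a latent timing (days) = clone genetic value + clone polygenic
deviation + block + year + environment + residual; stage *s* is reached
once the date passes `timing + offset(s) + ζ`, with per-stage jitter ζ and
a cumulative maximum keeping thresholds monotone.  Observed stages are
therefore ordinal, non-decreasing within a tree-year, and censored by the
visit calendar.  Heights are Gaussian around the genetic value.

Key defaults (units in parentheses):

| parameter | default | why |
|---|---|---|
| timing SD (days) | 6 | ~2-week spread of flush dates across a family |
| stage jitter SD (days) | 12 | sets the PC1 share of the day-to-stage covariance in the 50–73% range reported for such data; threshold censoring correlates adjacent stage columns, so this was fixed on draws of the generator itself |
| clonal repeatability | flush 0.45, set 0.43, height 0.60 | middle of the reported 0.33–0.57 / 0.33–0.54 / 0.49–0.80 ranges |
| block SD | 1 day / 5 mm | small relative to residual, as in a well-controlled clonal trial |
| planted PPVE | 3–16.4% flush, 2.7–22.2% set, 2.5–10.5% height | the reported per-trait ranges; one locus per trait is second-year-specific and one phenology locus indoor-only, to exercise the stability tabulations |

A QTL effect is stated in single-ramet phenotype SD; `effect_for_ppve`
converts a target share of clone-mean variance (the scan's response) into
that effect, `a = 2√(v · (R + (1−R)/k))` for repeatability R and k ramets.

What the generator does **not** emulate: photothermal physiology (no
temperature or photoperiod driving variables — environment enters only as
additive shifts and context-specific QTL activity), dominance and
epistasis, genotyping plate structure, and per-cross parental segregation
classes (both crosses share one class assignment and one planted-QTL list,
with per-cross marker subsets).  Passing tests therefore show the
*pipeline* recovers what it assumes about such data, not that real bud
phenology obeys the latent-timing model.

## Linkage mapping

Two-point θ̂ for same-parent testcross pairs is the phase-minimised
recombinant fraction, with
`LOD = k log₁₀ θ̂ + (n−k) log₁₀(1−θ̂) + n log₁₀ 2` (checked against a
numeric MLE oracle).  Markers failing a χ² 1:1 test at α = 0.01 are removed
before assembly.  Groups are connected components of the LOD ≥ 6.0 ∧
θ ≤ 0.35 graph.  Ordering minimises the sum of adjacent recombination
fractions — exhaustive for groups of ≤ 7 markers (verified equal to the
enumeration oracle), greedy nearest-neighbour seeding plus 2-opt otherwise;
missing pairwise estimates count as θ = 0.5.  Groups are numbered by
decreasing size and oriented so the smallest anchor id sits nearer 0; ties
break by marker id; positions are reported to 0.1 cM.

Merging aligns each map's matched group to the first map's frame by
orientation (correlation sign) and translation (shared-anchor centroid),
drops order-discordant anchors by a longest-increasing-subsequence filter,
averages anchor positions, and places non-anchor markers by homothetic
interpolation between flanking anchors (terminal-pair extrapolation at the
ends).  Scale is deliberately *not* normalised away — merging a map with a
map of twice its length yields the mean frame (1.5× spacing) — because the
merged map should average the parental recombination landscapes.  Groups
with fewer than two usable anchors are left unmerged and reported.

## Composite phenotypes

Day-to-stage conversion takes the earliest observation with recorded stage
≥ s (skipped stages inherit the first date at or after them); decreasing
sequences are repaired by cumulative maximum with a warning.  The PCA
operates on the pairwise-complete covariance of per-tree block means
(units missing more than half the stages are dropped, zero-variance columns
removed); components with eigenvalue strictly above 1 are retained, at most
three.  Varimax rotation is applied only when the two leading retained
eigenvalues are within a factor of 3 of each other: rotating a
strongly dominant first axis (the usual one-factor timing structure)
merely redistributes its variance and obscures the timing interpretation,
so rotation is reserved for the ambiguous case it is meant to fix.
Factorial scores are centred rows projected on the retained directions
(missing cells at the column mean); the dominant stage range collects
stages whose |loading| is ≥ 0.9 of the component's maximum.  Scores are
tested for normality (Lilliefors-corrected Kolmogorov–Smirnov, α = 0.05)
and the verdict is recorded with each component; scans run on all retained
components, with the verdict available for filtering.

Trait correlations use Pearson when both vectors pass the normality gate
and Spearman otherwise; magnitudes are classed small/medium/large at
0.1/0.3/0.5.  Clonal repeatability is the one-way ANOVA variance-component
ratio with the unbalanced n₀ correction.

## QTL scans

The scan engine is Haley–Knott regression: at each grid point (1 cM step
plus the marker positions) the expected allele origin given the nearest
non-missing flanking markers is computed with inverse-Kosambi recombination
probabilities chained across intervals; an observed call at the marker
itself is definitive.  `LOD = (n/2) log₁₀(RSS0/RSS1)`; at a fully observed
marker this equals the single-marker regression LOD exactly.  PPVE is
100 R² at the peak.

Thresholds: the response is permuted (≥ 1,000 times for reported runs,
fewer allowed in test mode) once per dataset; each permutation's maximum
LOD per group gives the chromosome-wise null and the overall maximum the
genome-wide null; the threshold is the ⌈(1−α)(n+1)⌉-th order statistic.
Calibration over 500 null genomes puts the genome-wide familywise error at
0.044 (band 0.03–0.07).  Peaks at or above the genome threshold are
significant, above the chromosome threshold suggestive.  Sub-threshold
candidates ("indicative") are recorded only when the peak is within 80% of
the chromosome threshold *and* the −1 LOD interval is narrower than half
the group — a flat profile's interval spans the whole group and would
co-localise with everything — and are retained only if that interval
overlaps at least two significant QTLs after projection.

Support intervals interpolate the −1/−2 LOD crossings linearly and
truncate at group ends; ties at the peak break leftmost.  In 200 replicate
crosses of 500 progeny with a planted 10%-PPVE locus, detection is 100%,
the −2 LOD interval covers the true position in ≥ 99% of detected cases,
and the mean estimated PPVE is within half a point of truth; at 250
progeny the mean estimated PPVE of detected QTLs exceeds the planted value
(the Beavis effect), as expected when detection conditions the estimate.

The two-linked-QTL check fits a two-position regression over a coarse grid
(5 cM, ≥ 15 cM separation, groups ≥ 40 cM only) and compares it to the
best single-QTL fit by permuting the single-fit residuals; the H1-vs-H0
decision uses the supplied single-QTL threshold.

The regression scan was cross-checked against an EM normal-mixture oracle
(the likelihood the regression approximates): for a typical small-effect
locus (~5% PPVE — the modal effect size in a large cross) on a 5 cM map,
the two agree within 0.2 LOD at every grid point.  The agreement band
degrades for strong QTLs (PPVE ≥ 10%): away from the peak the mixture
genuinely captures residual bimodality the regression cannot, with
discrepancies up to ~0.5 LOD — a known property of the Haley–Knott
approximation, not an implementation error.

## Projection, clusters, stability

Anchor frames pair each parental group's shared markers with their
composite positions; order-discordant anchors are removed by LIS (which is
exactly the "use the next flanking markers" fallback).  A position maps
linearly between its flanking anchors; ends extrapolate with the terminal
pair's ratio, capped at the composite group span.  Interval endpoints are
projected independently and swapped (with a warning) if inverted.

Two projected QTLs of one trait belong to the same cluster when their
−1 LOD intervals overlap on the same composite group *and* the overlap
contains at least one composite-map marker; clusters are connected
components of this relation (the seed-free choice — membership does not
depend on which QTL is examined first).  Stability flags: population-
replicated (members span both crosses), year-replicated (≥ 2 years within
a cross), environment-replicated (both block environments), plus
indoor-/outdoor-specific counts; percentages round half-up to integers.

## Co-location

The statistic for a pair of overlapping clusters of two traits is the
proportion of their member −1 LOD intervals that overlap an interval of the
other trait (closed intervals, same group).  The null re-places every
interval of both traits 1,000 times across the whole map — group drawn with
probability proportional to group length among groups long enough to hold
the interval, start uniform, length preserved; a within-group variant is
available by flag.  Significance uses the add-one exceedance estimator
((#null ≥ observed + 1)/(n+1) < 0.05).  Testing is per overlapping cluster
pair: pooling all intervals of two traits genome-wide saturates the null
and can never reject, whereas the cluster-pair statistic matches how such
overlaps are actually reported.  Under its own null generator the test
rejects at 0.048 (500 runs; the discreteness of the proportion makes it
slightly conservative).  End to end — simulate, rebuild the map, scan two
traits, project, test — a shared causal locus is flagged in ≥ 90% of
replicates and independent loci in ≤ 5%.

## Problem sizes

The default test and acceptance runs use scaled-down genomes (2–6 groups of
90–120 cM, crosses of 70–500 progeny, 120–300 permutations in test mode)
chosen so every claim is still measured with adequate replication: 500
simulations for error rates, 100–200 replicates for recovery rates.  The
`analysis/` drivers use 12 groups and crosses of 150/250 progeny with 500
permutations.  Full study-scale runs (12 × 175 cM, 260/500 progeny, 1,000
permutations) go through the same code paths via `run_pipeline` with a
larger configuration.

## Known limitations

* The recombination model carries only the interference implicit in the
  Kosambi function applied per interval; simulated double-recombinant
  rates in wide intervals are those of the Markov chain, not of a full
  interference model.
* Haley–Knott PPVE and LOD are approximations to the mixture likelihood;
  see the oracle band above.
* The merge procedure averages positions on the anchor frame; it is not a
  multipoint maximum-likelihood consensus map.
* The indicative-candidate floor (80% of the chromosome threshold, interval
  narrower than half the group) is a pragmatic screen; the class exists
  only to feed the co-localisation retention rule.
* No dominance, epistasis, G×E beyond on/off QTL contexts, or missing-by-
  design genotyping.
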