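# Methods

## Coalescent-with-recombination simulation

ARGs are generated by Hudson's back-in-time algorithm. Each lineage
carries a list of ancestral segments over the half-open boundary interval
[0, L); pairs coalesce at rate 1/Ne per pair (time in units of Ne
generations, Ne = 1 throughout), and each lineage recombines at rate
r·(span of its ancestral material). Recombination positions are continuous
and snapped to the nearest integer boundary, ties downward; a position
falling outside a lineage's ancestral span is a no-op and is not counted
as an event. Coalescences record edges (interval, parent, child) exactly
where the two lineages' material overlaps, and intervals in which all n
samples have coalesced are dropped from further tracking. Local trees are
extracted per interval from the edge table, with intervals split at every
distinct event breakpoint (so adjacent trees are identical across a pure
Type I breakpoint, by design).

**Event typing.** Each recombination event's two parent lineages (the
carriers of the genomic points just left and right of its breakpoint) are
followed forward through subsequent recombinations. The first coalescence
involving a carrier decides Type I (it joins the two carriers directly);
otherwise the second relevant coalescence decides Type II (the merged
lineage immediately joins the other carrier) versus Type III (anything
else). This per-event rule is applied identically in single- and
multi-event ARGs.

**Conditioning.** Event-count constraints, the requirement that each
event's recombinant material belong to exactly one sample (so a unique
recombinant child sequence exists; used in the triplet study), and the
exclusion of ARGs containing undetectable Type I events (multi-breakpoint
study) are all imposed by rejection with a cap of 1e5 attempts. Rejection
leaves the within-constraint distribution untouched, which the test suite
checks against unconditioned simulation filtered post hoc.

**Mutation.** Sequences evolve site-independently under the single-rate
equal-frequency model: P(same | t) = 1/4 + 3/4·e^(−4μt/3), with
μ = π/(2Ne) so that π is the expected pairwise diversity before
saturation. Root states are uniform per local-tree interval, and intervals
concatenate in genomic order. The generator is calibrated against the
closed-form coalescent expectations (mean event count r·L·E[tree length];
mean pairwise difference π/(1+4π/3) for n = 2) and was cross-checked
against an established coalescent simulator during development.

**What the generator does not emulate.** No gene conversion, population
structure, recombination-rate variation, indels, rate heterogeneity across
sites, or base-composition bias. Passing tests therefore speak to the
idealized regime the study targets; on real data, homoplasy from rate
variation and selection will add inconsistent informative sites beyond
what these simulations produce.

## Detectors

All detectors operate truth-blind on the alignment; α = 0.05 throughout.

**Pairwise χ² scan.** For a sequence pair, boundaries k = 1..L−1 index
2×2 tables of (differing, matching) counts left/right of k. Significance
is assessed by permuting site order: 1,000 permutations of the maximum
statistic, p = (1+exceedances)/(1+permutations), run in batches of 100
with early stopping once the exceedance count already guarantees p > α
(the detection decision is identical to the full run; only nonsignificant
p-values are reported at coarser resolution). Two numerical choices
matter:

- *Margin guard.* Boundaries leaving fewer than 5 differing sites on
  either side produce near-degenerate tables whose χ² spikes dominate both
  the observed scan and its permutation null; the test statistic therefore
  maximizes only over boundaries with ≥ 5 differing sites per side.
- *Unguarded estimate.* The reported breakpoint is the unrestricted
  argmax: applying the guard to the estimate would bias it away from true
  breakpoints adjacent to diff-sparse flanks (at low diversity the nearest
  admissible boundary can sit tens of bp away).

On a detection the scan recurses into both flanks until no further
boundary is significant, so multiple breakpoints per pair are reported.
Across pairs the per-pair level is Dunn–Šidák adjusted.

**Triplet exact test.** Sites where the candidate child matches exactly
one parent define the ±1 walk; the statistic is the maximum descent, and
its p-value is exact under uniformly random step orderings, computed by a
dynamic program over (up-steps used, current drawdown) that propagates
probability mass directly (no large combinatorial counts). Both parental
orderings are examined; the better direction's p-value is Šidák-adjusted
for the two looks, and across tests the number of (triplet, child)
assignments is Šidák-corrected. For long walks (≥ 60 informative sites) a
200-permutation Monte-Carlo screen skips the exact program when the
estimated p-value is ≥ 0.05 — far above any level that could survive
correction — so the exact computation is reserved for walks that could
matter; screened p-values never produce detections. Two reporting
conventions mirror the field's triplet tool:

- one record per candidate recombinant child (the lowest-p parent pair);
- the breakpoint interval is the uninformative gap at the walk's
  maximum-likelihood two-rate changepoint (the split of the step sequence
  into two independent Bernoulli segments maximizing the profile
  likelihood). For a clean parent-then-parent mosaic this is exactly the
  gap bounding the maximal descent; when the walk drifts, the descent's
  extreme points chase noise far from the affinity change while the
  changepoint remains anchored to it. The point estimate is the gap
  midpoint.

**AICc incongruence scan.** Distances are JC-corrected observed
differences (capped below saturation), trees are neighbor joining with
negative branch-length estimates clamped to zero, and segment
log-likelihoods come from Felsenstein pruning under the same
equal-frequency single-rate model with NJ branch lengths as-is. Parameter
counts are 2S−3 branch lengths per segment tree (no free substitution
parameters under JC); N is the full alignment length. Single-breakpoint
mode scans every candidate boundary (stride 1 for triplets; stride 10 and
minimum segment 20 for the 10-taxon studies, a cost/resolution trade-off);
multi-breakpoint mode adds breakpoints greedily while the total AICc
improves, up to the breakpoint budget. The site-wise profile is the Akaike
weight over candidate boundaries; the χ² scan's profile is its normalized
statistic curve; the triplet test's profile is uniform within the reported
gap.

## Evaluation

Localization error is |estimate − true| in bp. In the single-breakpoint
study a method's error is the smallest over its reported breakpoints, and
the headline table restricts to true breakpoints ≥ 400 bp from the
alignment ends (near the ends, error is mechanically bounded for accurate
methods and mechanically large for coarse ones). In the multi-breakpoint
study each reported event is matched against the breakpoints *visible to
the sequences it involves*: the marginal genealogy of the reported pair or
triplet is extracted per interval (canonically, as the set of
(clade, MRCA-time) pairs over the subset) and a breakpoint is visible iff
that restriction changes across it; the alignment-wide AICc scan is
matched against all true breakpoints. A reported pair/triplet whose
sub-ARG contains no visible event is a false positive and contributes no
error term. Each error term carries the matched true event's type, and
per-simulation means are averaged across simulations.

Precision treats a detector's normalized site profile as a distribution
over positions 1..L and reports 1/variance; profiles more concentrated
than a single site are capped at 12 (the reciprocal of the 1/12
quantization variance), so a point mass is the maximum.

## Feature regression

The five predictors are realized alignment diversity; event type (Type III
indicator, Type II as reference); mean |informative site − breakpoint|;
and ln(1 + count) of consistent and inconsistent informative sites (the
+1 admits zero counts). True triplet roles come from the ARG: the child is
the sample under the recombinant lineage; the left/right source samples
are its nearest neighbors (smallest TMRCA) in the flanking local trees.
When both sides trace to the same sample (the Type II configuration in a
triplet), that sample is P and the remaining one is Q, so P/Q-likeness
stays defined and all Q-matching sites are inconsistent — which is exactly
the Type II situation: the child inherited nothing from Q. The feature
table is built on the same edge-filtered estimand as the error table,
because edge proximity caps or inflates error in a way none of the five
predictors can express; Type I simulations and undetected replicates are
excluded. The response is the raw error in bp.

The PLSR is single-response NIPALS on standardized predictors: each factor
is the unit covariance-maximizing direction, X and y are deflated between
factors, πᵢ is factor i's share of the response variance, and
p_j = Σᵢ (w²ᵢⱼ/wᵢ)πᵢ partitions the total explained variance exactly
(unit-norm weights make Σⱼ p_j = Σᵢ πᵢ an identity, asserted to 1e-10).
Coefficients are reported back on the original predictor scale;
uncertainty comes from a case-resampling bootstrap with percentile
intervals (degenerate resamples redrawn); k is 5 by default, with 10-fold
CV selection available.

## Phylogenetic evaluation

The exclusion window of W sites is centered on each breakpoint (⌈W/2⌉
left, ⌊W/2⌋ right); overlapping windows merge and kept segments shorter
than 20 sites join the excluded set. Per-segment trees are searched by NJ
start, per-branch length optimization (each branch's likelihood is
a + b·e^(−4t/3) given the flanking partials, so the 1-D optimum comes from
a monotone bisection), and greedy NNI with the central branch re-optimized
per candidate swap; accepted moves always increase the likelihood, so the
returned tree is never worse than the NJ start. Segments with no variable
sites return the NJ tree flagged degenerate. RF distances are bipartition
symmetric differences normalized by 2(n−3); sites in excluded windows are
scored with the neighboring segment's tree on their side of the window
midpoint (single-neighbor at the genome edges). The summary reports both
the per-site mean and the variant weighting each true local tree equally.
A replicate in which a method detects nothing contributes the unsliced
baseline for that method.

## Problem sizes

The packaged studies run at desk scale: 100 replicates per
(diversity, rate) setting over the full single-breakpoint grid (1,800
simulations); ~90 replicates of the multiple-breakpoint study at
diversity ≥ 0.2 across all three recombination rates; and ~54 replicates
for the slicing evaluation over windows {0, 50, 100, 200}. All
per-replicate RNG streams derive from one master seed, so every table is
bit-reproducible.

## Known limitations

- The AICc scan's decision rule (joint two-tree versus one-tree model
  comparison) is more conservative than the original genetic-algorithm
  tool it emulates: its multi-breakpoint detection rate is high but not
  universal (a few percent of replicates with weak realized diversity or
  edge-clustered events go undetected), and neither per-segment
  branch-length optimization nor a finer candidate grid changes this —
  the misses are information-limited under these simulation conditions.
- Type II error cells in the multi-breakpoint table rest on few matched
  events (Type II breakpoints are rarely the nearest match to a reported
  boundary), so their means are volatile across seeds.
- The share of localization-error variance the five features explain is
  method-dependent here: the triplet test's errors are well explained
  (~40–45%), while the χ² and AICc scans' errors are dominated by
  case-specific mislocalization that the features do not capture
  (~10%). Relatedly, the bootstrap signs of the consistent/inconsistent
  coefficients are stable only for the triplet test at these sample
  sizes. The acceptance checks report these quantities as computed.
- Breakpoint probability profiles are working definitions (normalized χ²
  curve, uniform-in-gap, Akaike weights); other choices would change
  precision values but not their ordering across methods.
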