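# Methods

## Data model

A lineage forest is a set of rooted binary trees of tracked cells.  Cells
either have no tracked children or exactly two; generations are 1-based
(founder = 1).  A duration enters statistics only for *complete* cells —
those imaged from the end of the mitosis that created them through the
completion of their own mitosis.  Incomplete cells (alive when imaging
ends) keep their place in the topology but contribute nothing, and their
descendants are by definition unobserved.  Granddaughter sets require all
four grandchildren complete; the daughters' own completeness is irrelevant
because only the grandchildren's durations are compared.  Duration ties in
the set ordering are broken by lexicographic cell id, which makes all
downstream results deterministic.

Quality censoring (`censor_suspect_lineages`) removes every lineage
containing one of the k shortest complete durations in the data set —
implausibly short durations usually indicate tracking errors, and one
error casts doubt on its whole lineage.  Ties at the k-th shortest are all
included and the realized count is reported, since stopping mid-tie would
make the censored set depend on sort order.

## Outlier detection method

For four scalars the "variance-scaled distance" (univariate Mahalanobis
distance) is |dᵢ − dⱼ|/s.  We use the ddof = 1 sample SD of the four set
durations; the choice of divisor cancels in the dissimilarity index, which
is a ratio of two merge heights, so motif calls do not depend on it (and
are invariant under any affine rescaling d → a·d + b, a > 0, of a set).

Single linkage on four *sorted* scalars reduces exactly to the three
adjacent gaps: the merge heights are the sorted gaps, and cutting the last
merge splits the sequence at the largest gap, so both sides of the top
split are contiguous runs — a split isolating cell2 or cell3 alone, or
interleaving {1,3}|{2,4}, cannot occur.  The implementation uses this
reduction (it is what makes 10,000-permutation ensembles cheap); the test
suite verifies it against scipy's general single-linkage routine and
against exhaustive enumeration of all seven bipartitions (the top split
maximizes the minimum cross-cluster distance, the minimum-spanning-tree
characterization of single linkage).

Numerical edge cases, all classified **flat**: a dissimilarity index
exactly at the threshold (the rule requires strictly greater); tied top
gaps (these force an index of 1); three or more equal durations (the
second-highest merge height is 0, the index undefined); zero-variance
sets.  When tied largest gaps make the top split ambiguous the balanced
middle cut is reported — by the argument above this can never change a
motif call.  The default threshold is 2: above 2 the gap between the two
top-level sub-clusters exceeds the sum of the smallest pairwise distances
within the rest of the set.  The sweep grid 1.5, 2, 2.5, 3, 3.5, 4, 7
probes robustness of motif frequencies to this choice.

## Propagation test

Within-generation permutation is the null: complete durations are
reassigned by a uniform permutation among each generation's complete
cells across all lineages, keeping topology, so per-generation duration
multisets are conserved and the division-type counts under the null
reflect only where durations happen to land in the fixed trees.

Step (ii) needs the null distribution of the per-type probability
statistic.  We reuse the single ensemble: every permuted matrix is scored
against the full-ensemble CDF, rather than nesting a fresh inner ensemble
per outer matrix.  This keeps cost linear in the number of permutations;
the plug-in bias is small (a nested cross-check at small permutation
counts is part of the test suite) and identical for the empirical and the
pseudo-empirical scores, which is what the comparison uses.

Interval endpoints on the discrete null distributions are inclusive
order-statistic (type-1) quantiles — the ⌈0.025·n⌉-th and ⌈0.975·n⌉-th
order statistics — and "outside" is strict.  Ties at an endpoint therefore
never fire.  Two consequences, both deliberate and conservative:

* The displayed per-type "empirical probability" is a CDF value
  P(count ≤ observed), not a p-value; two-sidedness is realized by the
  step-(ii) interval, not by doubling.
* Division-type counts are small integers with heavy ties, so appreciable
  null probability mass sits exactly on the interval endpoints and the
  realized per-type false-positive rate is *below* the nominal 5% (about
  2–3% at the calibration suite's problem size).  The honest calibration
  check is one-sided — the flag rate must not exceed nominal — and that is
  what the acceptance suite asserts.  The step-(iv) joint decision
  (per-type *and* global criterion at 5%) is likewise ≤ 5% under the null.

One seeded generator drives each run; ensembles, results and serialized
JSON are bit-reproducible from (forest, threshold, n_perm, seed).

## Effect sizes and summaries

rz-scores use the raw median absolute deviation (no 1.4826 consistency
factor): between two conditions, |Δ median| over the mean of the two MADs
(a value near 1 means the medians differ by about one MAD — as large as
the typical distance of a data point from its own median); for one
division type, |observed − null median| / null MAD with the null counts
from the permutation ensemble.  In the planted-alternative simulations the
matrix-wide maximal estimated rz always belongs to a significant type, and
the planted type's median rz across replicates is well above 3.

IDR/median uses linearly interpolated empirical quantiles (the 10th/90th
percentiles), pinned in tests by a direct order-statistic computation.
Granddaughter–granddaughter correlation pairs default to cousins only
(members of one set with different mothers); within-set sibling pairs can
be included by flag, since the convention is a genuine ambiguity.
Spearman correlations are computed on repeated 60-pair subsamples (100
repetitions) so conditions with different pair counts are comparable.

## Colony metrics

The colony boundary is a concave hull with a shrink factor in [0, 1]:
0 gives the convex hull, 1 the tightest single-region hull still
containing all points (realized via shapely/GEOS's concave hull with
ratio = 1 − shrink).  This reproduces the contract of the boundary routine
used in the original tracking environment — shrink interpolating convex
to tightest — not its exact vertex set, which is not specified anywhere;
tests therefore pin the convex end against an independent hull
implementation and check containment, monotonicity and rigid-motion
invariance rather than vertex identity.  Degenerate frames (< 3 points or
collinear) make every cell a boundary cell.  Circularity is 4πA/P²
(1 for a disc, π/4 for a square — the formula is our choice, pinned by
those closed forms).  Trend estimation uses iteratively reweighted least
squares with the Tukey bisquare weight (c = 4.685, median-absolute-residual
scale, ≤ 50 iterations, tolerance 1e−8) via statsmodels RLM.

## Synthetic data

The generator emulates what the analysis assumes about tracked colonies:
binary trees to at most 7 generations; log-normal durations (positive,
right-skewed) drawn independently within each generation, with
generation-specific medians available; censoring by cumulative birth time
against an imaging horizon.  Defaults encode the primary study conditions:
36 lineages, 16.2 h median, 85 h horizon.  The default log-scale SD is
0.22, chosen so that (a) marginal dispersion is realistic for epithelial
cell cycle data (IDR/median ≈ 0.57) and (b) a 3-fold duration change — the
operating point of the recovery requirement — is reliably separable by the
ODM from sibling noise (measured recovery ≈ 94%); a broader noise scale
would push 3× outliers under the threshold in a material fraction of sets.

The `outlier_propagation` mechanism plants the alternative: per
grandmother, with probability `rate`, exactly one of the four prospective
granddaughters has its duration multiplied by `outlier_effect` (or its
inverse for a short-outlier target), *before* that cell's own completeness
and children are resolved.  Selection is per granddaughter set — at rate
1.0 almost every complete set carries exactly one relative outlier and
classifies 3:L — and `source_class` chooses whether the perturbed branch
prefers an unperturbed mother (de-novo generation from 0-cells) or an
already-perturbed one (outlier chains across generations).  Ground truth
records every perturbed cell.  Note the multiplicative asymmetry: a 1/3
scaling moves a short cell by far fewer hours than a 3× scaling moves a
long one, so 3:S recovery is intrinsically weaker than 3:L at the same
nominal effect — visible in the test suite's expectations.

What the generator does **not** emulate: mother–daughter duration
correlations under the null (real lineages show positive kinship
correlations even without outlier propagation), generation trends enabled
by default, cell death, non-binary divisions, or mechanistic cell-cycle
phase structure.  Passing calibration on these synthetic forests shows the
test keeps its nominal level under exchangeability — it does not show how
the test behaves under correlated-but-symmetric inheritance, which is a
known limitation.

Tracks are a cohesive random walk (attraction to the colony centroid plus
isotropic Gaussian noise; daughters start adjacent to their mother),
sufficient for exercising the boundary/periphery/velocity metrics, not a
model of epithelial migration.

## Problem sizes

Default permutation depth is 10,000 (seconds at the 36-lineage scale,
thanks to the vectorized engine).  The calibration suite uses 200
replicate null forests of 30 fully imaged 5-generation lineages at 500
permutations each; the power/recovery suite 20 replicates of the planted
mechanism (rate 0.8, effect 3.0) at 500 permutations.  These sizes give
binomial Monte-Carlo error small enough for the one-sided 5% checks while
keeping the full suite fast.
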