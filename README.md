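# lineagemotifs

Statistics of cell cycle duration variability in single-cell lineage trees:
diversity motifs among granddaughter cells, and a Monte-Carlo permutation
test for whether the divisions that generate relative outlier cells occur
non-stochastically.

## The problem

Time-lapse tracking of clonally dividing cells (epithelial cell colonies,
stem cells, bacteria) yields binary lineage trees in which every fully
imaged cell carries one number: its cell cycle duration, the time from the
end of the mitosis that created it to the completion of its own mitosis.
Durations of related cells are strikingly variable, and the question this
package addresses is whether that variability is propagated from mother to
daughter — i.e. whether some divisions are *asymmetric* in a way that is
incompatible with durations being randomly exchangeable among the cells of
a generation.

## The method

**Granddaughter sets and the outlier detection method (ODM).**  For every
grandmother cell whose four grandchildren were completely imaged, the four
durations are ordered ascending (cell1 ≤ … ≤ cell4) and compared by
variance-scaled pairwise distances d(i,j) = |dᵢ − dⱼ|/s (s = sample SD of
the four values), clustered by single linkage.  The **dissimilarity
index** is the ratio of the highest to the second-highest merge height.
If it exceeds a threshold (default 2) the top bipartition decides the
motif: cell4 isolated → **3:L** (a relatively long outlier, the L-cell);
cell1 isolated → **3:S** (S-cell); {cell1,cell2}|{cell3,cell4} → **2:2**;
otherwise the set is **flat**.  Set members that are not outliers are
0-cells.

**Division types and the propagation test.**  Each classified mother and
its two classified daughters form a division type: S/L/0 mother → daughter
pair 0/0, S/0 or L/0 (S/S, L/L and S/L pairs are structurally impossible —
both daughters sit in one granddaughter set, which has at most one
outlier).  The null hypothesis is that durations are exchangeable within
each generation across all lineages.  The test: (1) permute all complete
durations within each generation (10,000 times, topology fixed) and
recount the 3×3 division-type matrix; (2) per type, the empirical
probability is the null-CDF value of the observed count; a type is
significant when that probability falls outside the central 95% of the
probability statistic's own null distribution; (3) the number of
significant types is compared to its permutation null, giving a global
p-value P(≥ observed #significant); (4) a type is colour-coded
(over-/under-represented) only when both the per-type and the global
criterion are met at the 5% level.  Effect sizes are robust rz-scores:
|observed − median(null)| / MAD(null).

The package also provides the supporting analyses: kinship-pair
(mother–daughter, sibling, cousin) subsampled Spearman correlations,
IDR/median dispersion, short-duration lineage censoring, colony-shape
metrics on centroid tracks (concave-hull boundary, periphery index,
circularity 4πA/P² with robust time trends, median velocities), and a
synthetic generator producing lineage forests with the exchangeable-null
structure or a planted outlier-propagation mechanism.

## Worked example

```python
import lineagemotifs as lm

# simulate 30 fully imaged 5-generation lineages with a planted
# mother-to-daughter outlier mechanism (one 3x-duration granddaughter per
# set at rate 0.8), then test for non-stochastic propagation
cfg = lm.ForestSimConfig(n_lineages=30, max_generation=5,
                         imaging_horizon_h=1e6,
                         mechanism=lm.OutlierPropagation(rate=0.8,
                                                         outlier_effect=3.0))
sim = lm.simulate_forest(cfg, rng=21)
calls = lm.classify_forest(sim.forest)            # ODM at threshold 2
res = lm.run_propagation_test(sim.forest, n_perm=10_000, rng=22)
print(len(calls), res.global_.empirical_count, res.global_.p)
print(res.empirical.to_frame())
```

prints

```
210 5 0.0
to    0/0  S/0  L/0
from
S       0    0    1
L      69    0    4
0     136    5  145
```

210 granddaughter sets were classified; 5 of the 9 division types are
individually significant and the global p-value is < 1/10,000, so the
division-type pattern is incompatible with within-generation
exchangeability.  The planted 0 → L/0 type (145 of 360 divisions, null
median 75) is flagged over-represented; running the same test on a forest
without the mechanism yields no significant types and a global p of 1.

The same pipeline runs from the shell on lineage-table CSVs
(`lineagemotifs simulate | classify | propagate | correlate | colony`),
and `analysis/01…05` are narrative drivers that write the full set of
tables under `results/`.

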