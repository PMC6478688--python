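"""Outlier detection method: distances, single linkage, motif assignment.

The production path reduces single linkage on four sorted scalars to the
three adjacent gaps; these tests pin it against three independent oracles:
a covariance-based Mahalanobis computation, scipy's general single-linkage
routine, and exhaustive enumeration of all two-cluster bipartitions.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage

import lineagemotifs as lm
from lineagemotifs.core import GranddaughterSet, build_forest
from lineagemotifs.motifs import (Motif, motif_frequencies, motif_frequency_sweep,
                                  motif_confidence_band, pairwise_scaled_distances,
                                  single_linkage_hierarchy, dissimilarity_index,
                                  classify_set)

from conftest import make_binary_lineage, set_lineage


def gset(durations):
    d = tuple(sorted(float(x) for x in durations))
    return GranddaughterSet("gm", ("c1", "c2", "c3", "c4"), d)


def brute_force_mahalanobis(durations):
    """1-D Mahalanobis distances via the covariance-matrix definition."""
    d = np.asarray(durations, dtype=float)
    cov_inv = 1.0 / np.cov(d)  # ddof=1
    out = []
    for i, j in itertools.combinations(range(4), 2):
        diff = d[i] - d[j]
        out.append(np.sqrt(diff * cov_inv * diff))
    return np.array(out)


def exhaustive_top_split(durations):
    """Bipartition maximizing the minimum cross-cluster scaled distance.

    Single linkage equals the minimum spanning tree; cutting its largest
    edge yields the two-cluster partition with maximal min-linkage, found
    here by enumerating all 7 bipartitions of the 4 sorted points.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    s = d.std(ddof=1)
    best, best_h = None, -1
    for size in (1, 2):
        for left in itertools.combinations(range(4), size):
            right = tuple(i for i in range(4) if i not in left)
            h = min(abs(d[i] - d[j]) / s for i in left for j in right)
            if h > best_h:
                best_h, best = h, (tuple(i + 1 for i in left),
                                   tuple(i + 1 for i in right))
    return frozenset(map(frozenset, best)), best_h


class TestScaledDistances:
    def test_zero_variance_gives_zero_distances(self):
        assert np.array_equal(pairwise_scaled_distances([10, 10, 10, 10]), np.zeros(6))

    def test_matches_covariance_based_oracle(self, rng):
        for _ in range(200):
            d = rng.uniform(1, 50, 4)
            np.testing.assert_allclose(
                pairwise_scaled_distances(d), brute_force_mahalanobis(d), rtol=1e-12)

    def test_first_pair_distance_example(self):
        d = (10, 11, 12, 30)
        s = np.std(d, ddof=1)
        assert pairwise_scaled_distances(d)[0] == pytest.approx(1 / s)

    @given(st.floats(0.1, 100), st.floats(-50, 50), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        d = np.random.default_rng(seed).uniform(1, 50, 4)
        np.testing.assert_allclose(
            pairwise_scaled_distances(a * d + b),
            pairwise_scaled_distances(d), rtol=1e-7, atol=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pairwise_scaled_distances([1, 2, 3, np.nan])


class TestSingleLinkage:
    @pytest.mark.parametrize("durations, gap_ratios, split", [
        ((10, 11, 12, 30), (1, 1, 18), ((1, 2, 3), (4,))),
        ((10, 12, 28, 30), (2, 2, 16), ((1, 2), (3, 4))),
        ((5, 6, 7, 8), (1, 1, 1), ((1, 2), (3, 4))),
    ])
    def test_examples(self, durations, gap_ratios, split):
        h = single_linkage_hierarchy(durations)
        expected = np.sort(gap_ratios) / np.std(durations, ddof=1)
        np.testing.assert_allclose(h.heights, expected, rtol=1e-12)
        assert h.top_split == split

    def test_matches_scipy_single_linkage(self, rng):
        for _ in range(500):
            d = np.sort(rng.uniform(1, 50, 4))
            h = single_linkage_hierarchy(d)
            Z = linkage(pairwise_scaled_distances(d), "single")
            np.testing.assert_allclose(np.sort(Z[:, 2]), h.heights, rtol=1e-9)
            labels = fcluster(Z, 2, "maxclust")
            scipy_split = frozenset(
                frozenset(np.flatnonzero(labels == k) + 1) for k in (1, 2))
            assert scipy_split == frozenset(map(frozenset, h.top_split))

    def test_matches_exhaustive_bipartition_oracle(self, rng):
        for _ in range(2000):
            d = np.sort(rng.uniform(1, 50, 4))
            h = single_linkage_hierarchy(d)
            oracle_split, oracle_height = exhaustive_top_split(d)
            assert frozenset(map(frozenset, h.top_split)) == oracle_split
            assert h.heights[2] == pytest.approx(oracle_height)

    def test_top_split_contiguous_never_interleaved(self, rng):
        for _ in range(500):
            d = np.sort(rng.uniform(1, 50, 4))
            left, right = single_linkage_hierarchy(d).top_split
            for side in (left, right):
                assert list(side) == list(range(side[0], side[-1] + 1))
            assert frozenset(map(frozenset, (left, right))) not in (
                frozenset([frozenset([1, 3]), frozenset([2, 4])]),
                frozenset([frozenset([1, 4]), frozenset([2, 3])]),
            )


class TestDissimilarityIndex:
    @pytest.mark.parametrize("durations, expected", [
        ((10, 11, 12, 30), 18.0),
        ((10, 12, 28, 30), 8.0),
        ((5, 6, 7, 8), 1.0),
    ])
    def test_ratio(self, durations, expected):
        h = single_linkage_hierarchy(durations)
        assert dissimilarity_index(h) == pytest.approx(expected)

    def test_undefined_for_degenerate_spread(self):
        h = single_linkage_hierarchy((7, 7, 7, 9))
        assert dissimilarity_index(h) is None


class TestClassifySet:
    @pytest.mark.parametrize("durations, motif, outlier_rank", [
        ((10, 11, 12, 30), Motif.THREE_L, 3),
        ((2, 20, 21, 22), Motif.THREE_S, 0),
        ((10, 12, 28, 30), Motif.TWO_TWO, None),
        ((5, 6, 7, 8), Motif.FLAT, None),
        ((10, 10, 10, 10), Motif.FLAT, None),
    ])
    def test_rules(self, durations, motif, outlier_rank):
        s = gset(durations)
        call = classify_set(s, 2.0)
        assert call.motif is motif
        if outlier_rank is None:
            assert call.outlier_id is None
        else:
            assert call.outlier_id == s.members[outlier_rank]

    def test_index_exactly_at_threshold_is_flat(self):
        # gaps 1, 1, 2 -> index exactly 2
        call = classify_set(gset((10, 11, 12, 14)), 2.0)
        assert call.dissimilarity_index == pytest.approx(2.0)
        assert call.motif is Motif.FLAT

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_set(gset((1, 2, 3, 4)), 1.0)


class TestForestClassification:
    def test_empty_forest_gives_no_calls(self):
        f = build_forest(make_binary_lineage("L1", 2))
        assert lm.classify_forest(f) == []

    def test_planted_motifs_recovered(self, toy_forest):
        calls = {c.set_ref.grandmother_id: c for c in lm.classify_forest(toy_forest)}
        assert calls["A.1"].motif is Motif.THREE_L and calls["A.1"].outlier_id == "A.7"
        assert calls["B.1"].motif is Motif.THREE_S and calls["B.1"].outlier_id == "B.4"
        assert calls["A.2"].motif is Motif.FLAT
        assert calls["B.2"].motif is Motif.TWO_TWO

    def test_scale_invariance_of_calls(self, toy_forest):
        scaled = toy_forest.with_durations(
            {c.cell_id: 1.7 * c.duration for c in toy_forest.complete_cells()})
        original = [(c.set_ref.grandmother_id, c.motif, c.outlier_id)
                    for c in lm.classify_forest(toy_forest)]
        rescaled = [(c.set_ref.grandmother_id, c.motif, c.outlier_id)
                    for c in lm.classify_forest(scaled)]
        assert original == rescaled


class TestFrequencySweep:
    def test_single_three_l_set(self):
        f = build_forest(set_lineage("L1", [10, 11, 12, 30]))
        table = motif_frequency_sweep(f, [2.0])
        assert table.loc[2.0, "3:L"] == 1.0

    def test_planted_frequencies(self):
        sets = ([[10, 11, 12, 30]] * 6 + [[2, 20, 21, 22]]
                + [[10, 12, 28, 30]] + [[5, 6, 7, 8]] * 2)
        records = []
        for i, durations in enumerate(sets):
            records += set_lineage(f"L{i}", durations)
        table = motif_frequency_sweep(build_forest(records), [2.0])
        np.testing.assert_allclose(table.loc[2.0].to_numpy(), [0.6, 0.1, 0.1, 0.2])

    def test_rows_sum_to_one_and_flat_monotone(self, rng):
        sim = lm.simulate_forest(lm.ForestSimConfig(n_lineages=8), rng)
        table = motif_frequency_sweep(sim.forest, [2.0, 10.0])
        np.testing.assert_allclose(table.sum(axis=1), 1.0)
        assert table.loc[10.0, "flat"] >= table.loc[2.0, "flat"]


class TestConfidenceBand:
    def test_permutation_invariant_forest_collapses_band(self):
        # identical durations within each generation: permutation is a no-op
        records = []
        for lid in ("A", "B"):
            records += make_binary_lineage(lid, 3,
                                           durations={1: 10, 2: 8, 3: 8,
                                                      4: 5, 5: 5, 6: 5, 7: 5})
        f = build_forest(records)
        band = motif_confidence_band(f, [2.0], n_perm=50, rng=0)
        point = motif_frequencies(lm.classify_forest(f, 2.0))
        for motif, freq in point.items():
            assert band.loc[(2.0, motif.value), "lo"] == pytest.approx(freq)
            assert band.loc[(2.0, motif.value), "hi"] == pytest.approx(freq)

    def test_same_seed_reproduces_band(self, toy_forest):
        b1 = motif_confidence_band(toy_forest, [2.0, 3.0], n_perm=100, rng=7)
        b2 = motif_confidence_band(toy_forest, [2.0, 3.0], n_perm=100, rng=7)
        assert b1.equals(b2)

    def test_planted_signal_exceeds_upper_band(self):
        """A forest where outliers are injected one-per-set shows a 3:L
        frequency above the permutation band's 97.5% bound."""
        cfg = lm.ForestSimConfig(
            n_lineages=25, max_generation=5, imaging_horizon_h=1e6,
            mechanism=lm.OutlierPropagation(rate=1.0, outlier_effect=3.0))
        sim = lm.simulate_forest(cfg, 3)
        empirical = motif_frequencies(lm.classify_forest(sim.forest, 2.0))
        band = motif_confidence_band(sim.forest, [2.0], n_perm=300, rng=3)
        assert empirical[Motif.THREE_L] > band.loc[(2.0, "3:L"), "hi"]
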