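"""Within-generation permutation machinery and the four-step decision."""

import itertools
import json

import numpy as np
import pytest

import lineagemotifs as lm
from lineagemotifs.core import build_forest
from lineagemotifs.propagation import (ForestEngine, PermutationEnsemble,
                                       TYPE_LABELS, _order_stat_interval,
                                       build_ensemble, cdf_probability,
                                       global_significance, per_type_significance,
                                       permute_within_generations,
                                       propagation_result, run_propagation_test)

from conftest import make_binary_lineage


@pytest.fixture
def small_sim(rng):
    cfg = lm.ForestSimConfig(n_lineages=12, max_generation=5, imaging_horizon_h=1e6)
    return lm.simulate_forest(cfg, rng)


class TestPermutation:
    def test_generation_multisets_conserved(self, small_sim, rng):
        f = small_sim.forest
        pf = permute_within_generations(f, rng)
        assert f.generation_pools == pf.generation_pools

    def test_singleton_generation_unchanged(self, rng):
        f = build_forest(make_binary_lineage("L1", 3))
        pf = permute_within_generations(f, rng)
        assert pf.cells["L1.1"].duration == f.cells["L1.1"].duration

    def test_topology_and_completeness_untouched(self, small_sim, rng):
        f = small_sim.forest
        pf = permute_within_generations(f, rng)
        assert pf.children == f.children
        assert all(pf.cells[c].complete == f.cells[c].complete for c in f.cells)

    def test_engine_matches_record_level_permutation(self, small_sim):
        """The vectorized engine and the forest-level permuter draw
        identically from the same seed and give the same matrix."""
        f = small_sim.forest
        engine = ForestEngine(f)
        for seed in (0, 1, 99):
            slow = lm.forest_division_matrix(
                permute_within_generations(f, np.random.default_rng(seed))).counts
            fast = engine.matrices(
                engine.permuted_durations(np.random.default_rng(seed), 1))[0]
            assert np.array_equal(slow, fast)

    def test_engine_empirical_matches_record_level(self, small_sim):
        engine = ForestEngine(small_sim.forest)
        assert np.array_equal(engine.empirical_matrix().counts,
                              lm.forest_division_matrix(small_sim.forest).counts)


class TestEnsemble:
    def test_single_permutation_deterministic(self, small_sim):
        e1 = build_ensemble(small_sim.forest, n_perm=1, rng=5)
        e2 = build_ensemble(small_sim.forest, n_perm=1, rng=5)
        assert np.array_equal(e1.matrices, e2.matrices)

    def test_permutation_invariant_forest_reproduces_empirical(self):
        # equal durations within each generation -> permutation is a no-op
        records = []
        for lid in ("A", "B", "C"):
            records += make_binary_lineage(
                lid, 4, durations={n: float(10 + n.bit_length()) for n in range(1, 16)})
        f = build_forest(records)
        engine = ForestEngine(f)
        ens = build_ensemble(engine, n_perm=25, rng=0)
        emp = engine.empirical_matrix().counts
        assert all(np.array_equal(m, emp) for m in ens.matrices)

    def test_ensemble_mean_matches_exhaustive_enumeration(self):
        """Two 4-generation lineages with fixed (equal) generation-4 durations:
        permutations only act on the 8 generation-3 durations, so the exact
        mean division-type matrix follows from enumerating all 8! orderings."""
        gen3 = [10.0, 11.0, 12.0, 30.0, 13.0, 14.0, 15.0, 2.0]
        records = []
        for li, lid in enumerate(("A", "B")):
            durations = {n: 8.0 for n in range(8, 16)}  # generation 4: all equal
            durations.update({n: 20.0 for n in (1, 2, 3)})
            durations.update({n + 4: gen3[4 * li + n] for n in range(4)})
            records += make_binary_lineage(lid, 4, durations=durations)
        f = build_forest(records)
        engine = ForestEngine(f)

        perms = np.array(list(itertools.permutations(gen3)))
        base = np.tile(engine.durations, (len(perms), 1))
        gen3_idx = np.flatnonzero(engine.generations == 3)
        base[:, gen3_idx] = perms
        exact_mean = engine.matrices(base).reshape(len(perms), 9).mean(axis=0)

        ens = build_ensemble(engine, n_perm=4000, rng=11)
        mc_mean = ens.counts.mean(axis=0)
        # counts per type are in [0, 8]; MC error of the mean ~ sd/sqrt(4000)
        np.testing.assert_allclose(mc_mean, exact_mean, atol=0.15)


class TestCdfProbability:
    def test_observed_at_or_above_max_is_one(self):
        assert cdf_probability(5, [0, 1, 2]) == 1.0

    def test_observed_below_min_is_zero(self):
        assert cdf_probability(-1, [0, 1, 2]) == 0.0

    def test_direct_fraction(self):
        assert cdf_probability(2, [0, 1, 2, 3]) == 0.75

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            cdf_probability(1, [])


def test_order_stat_interval_inclusive_endpoints():
    values = np.arange(1, 101, dtype=float)  # 1..100
    lo, hi = _order_stat_interval(values)
    assert (lo, hi) == (3.0, 98.0)  # ceil(0.025*100)=3rd, ceil(0.975*100)=98th


class TestSignificance:
    def test_degenerate_ensemble_flags_nothing(self, small_sim):
        engine = ForestEngine(small_sim.forest)
        emp = engine.empirical_matrix()
        ens = PermutationEnsemble(
            n_perm=100, threshold=2.0,
            matrices=np.tile(emp.counts, (100, 1, 1)))
        records = per_type_significance(emp, ens)
        assert not any(r.significant for r in records)
        g = global_significance(ens, 0)
        assert g.p == 1.0 and g.histogram == {0: 1.0}

    def test_planted_enrichment_flagged_over(self, rng):
        cfg = lm.ForestSimConfig(
            n_lineages=30, max_generation=5, imaging_horizon_h=1e6,
            mechanism=lm.OutlierPropagation(source_class="0",
                                            target_pair_type="L/0", rate=0.8))
        sim = lm.simulate_forest(cfg, rng)
        res = run_propagation_test(sim.forest, n_perm=400, rng=17)
        idx = TYPE_LABELS.index("0->L/0")
        assert res.per_type[idx].significant
        assert res.per_type[idx].direction == "over"
        assert res.global_.p <= 0.05
        assert res.decisions[2][2] == "over"  # red cell at (0, L/0)

    def test_flags_reproducible_with_seed(self, small_sim):
        r1 = run_propagation_test(small_sim.forest, n_perm=200, rng=3)
        r2 = run_propagation_test(small_sim.forest, n_perm=200, rng=3)
        assert r1.to_dict() == r2.to_dict()

    def test_probabilities_in_unit_interval(self, small_sim):
        res = run_propagation_test(small_sim.forest, n_perm=200, rng=3)
        for t in res.per_type:
            assert 0.0 <= t.probability <= 1.0
            assert 0.0 <= t.interval[0] <= t.interval[1] <= 1.0

    def test_decision_requires_both_criteria(self, small_sim):
        res = run_propagation_test(small_sim.forest, n_perm=200, rng=3)
        for i in range(3):
            for j in range(3):
                d = res.decisions[i][j]
                t = res.per_type[i * 3 + j]
                if d is not None:
                    assert t.significant and res.global_.p <= 0.05
                    assert d == t.direction


def test_plug_in_null_close_to_nested_permutation_null(small_sim):
    """Step ii reuses the one ensemble (each permuted matrix scored against
    the full-ensemble CDF).  A nested version — each of 40 outer matrices
    scored against its own fresh 200-permutation inner ensemble — must give
    a similar null distribution of the probability statistic."""
    engine = ForestEngine(small_sim.forest)
    rng = np.random.default_rng(42)
    n_inner, n_outer = 200, 40

    ens = build_ensemble(engine, n_perm=n_inner, rng=rng)
    plug_in = np.empty((n_inner, 9))
    for t in range(9):
        s = np.sort(ens.counts[:, t])
        plug_in[:, t] = np.searchsorted(s, ens.counts[:, t], side="right") / n_inner

    outer = build_ensemble(engine, n_perm=n_outer, rng=rng)
    nested = np.empty((n_outer, 9))
    for k in range(n_outer):
        inner = build_ensemble(engine, n_perm=n_inner, rng=rng)
        for t in range(9):
            s = np.sort(inner.counts[:, t])
            nested[k, t] = np.searchsorted(s, outer.counts[k, t], side="right") / n_inner
    # compare medians of the null probability statistic per division type
    assert np.nanmax(np.abs(np.median(plug_in, axis=0)
                            - np.median(nested, axis=0))) < 0.2


def test_result_json_round_trip(small_sim, tmp_path):
    from lineagemotifs.io import read_propagation_json, write_propagation_json

    res = run_propagation_test(small_sim.forest, n_perm=100, rng=9)
    path = tmp_path / "result.json"
    write_propagation_json(res, path)
    again = read_propagation_json(path)
    assert again == res
    # same seed twice -> byte-identical file
    res2 = run_propagation_test(small_sim.forest, n_perm=100, rng=9)
    path2 = tmp_path / "result2.json"
    write_propagation_json(res2, path2)
    assert path.read_bytes() == path2.read_bytes()
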