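"""Similarity indices, Fisher enrichment, S_GO, IC, random null, mover stats."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from gcnrefine import (
    DegenerateDataError,
    EnrichmentResult,
    ExpressionMatrix,
    Partition,
    ValidationError,
    contingency_table,
    enrichment_table,
    fisher_enrichment,
    information_content,
    module_eigengenes,
    mover_mm_stats,
    partition_similarity,
    random_reassignment_null,
    relative_improvement,
    s_go,
)
from gcnrefine.io import GeneSetCollection

from conftest import random_partition


def pair_count_oracle(p, q):
    """All-pairs enumeration of rand and jaccard (independent oracle)."""
    a = b = c = d = 0
    for i, j in itertools.combinations(range(len(p.genes)), 2):
        same_p = p.labels[i] == p.labels[j]
        same_q = q.labels[i] == q.labels[j]
        if same_p and same_q:
            a += 1
        elif same_p:
            b += 1
        elif same_q:
            c += 1
        else:
            d += 1
    total = a + b + c + d
    rand = (a + d) / total if total else 1.0
    jacc = a / (a + b + c) if (a + b + c) else 1.0
    return rand, jacc


def hypergeom_tail_oracle(overlap, module, gset, universe):
    """Exhaustive hypergeometric upper-tail sum (independent oracle)."""
    total = 0.0
    for x in range(overlap, min(module, gset) + 1):
        total += (
            comb(gset, x, exact=True)
            * comb(universe - gset, module - x, exact=True)
        ) / comb(universe, module, exact=True)
    return total


class TestPartitionSimilarity:
    def test_identical_partitions_score_one(self, rng):
        p = random_partition([f"g{i}" for i in range(20)], 4, rng)
        for idx in ("rand", "jaccard", "matching"):
            assert partition_similarity(p, p, idx) == 1.0

    def test_three_gene_worked_example(self):
        p = Partition(["1", "2", "3"], [1, 1, 2])
        q = Partition(["1", "2", "3"], [1, 2, 2])
        # pairs: (1,2) disagree, (1,3) agree (apart in both), (2,3) disagree
        assert partition_similarity(p, q, "rand") == pytest.approx(1 / 3)

    def test_relabeling_invariance(self, rng):
        genes = [f"g{i}" for i in range(15)]
        p = random_partition(genes, 3, rng)
        relabeled = Partition(genes, [{0: 7, 1: 5, 2: 9, 3: 2}[int(l)] for l in p.labels])
        for idx in ("rand", "jaccard", "matching"):
            assert partition_similarity(p, relabeled, idx) == 1.0

    def test_matches_all_pairs_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for _ in range(50):
            p = random_partition(genes, int(rng.integers(1, 5)), rng)
            q = random_partition(genes, int(rng.integers(1, 5)), rng)
            rand_o, jacc_o = pair_count_oracle(p, q)
            assert partition_similarity(p, q, "rand") == pytest.approx(rand_o, abs=1e-14)
            assert partition_similarity(p, q, "jaccard") == pytest.approx(jacc_o, abs=1e-14)

    def test_matching_one_iff_relabeling(self, rng):
        genes = [f"g{i}" for i in range(10)]
        for _ in range(30):
            p = random_partition(genes, 3, rng)
            q = random_partition(genes, 3, rng)
            score = partition_similarity(p, q, "matching")
            is_relabel = partition_similarity(p, q, "rand") == 1.0
            assert (score == 1.0) == is_relabel

    def test_universe_mismatch_rejected(self):
        p = Partition(["a", "b"], [1, 2])
        q = Partition(["a", "c"], [1, 2])
        with pytest.raises(ValidationError):
            partition_similarity(p, q)

    def test_contingency_marginals(self, rng):
        genes = [f"g{i}" for i in range(25)]
        p = random_partition(genes, 3, rng)
        q = random_partition(genes, 4, rng)
        table = contingency_table(p, q)
        assert table.sum() == 25


class TestFisherEnrichment:
    def test_perfect_overlap_worked_example(self):
        universe = [f"g{i}" for i in range(20)]
        module = universe[:5]
        p, orr, overlap = fisher_enrichment(module, module, universe)
        assert overlap == 5
        assert p == pytest.approx(1 / comb(20, 5, exact=True), rel=1e-12)

    def test_null_overlap_near_one(self):
        # overlap at the hypergeometric mode with no effect: one-sided p >= 0.5
        universe = [f"g{i}" for i in range(40)]
        module = universe[:10]
        gset = universe[8 : 8 + 20]  # overlap 2 = mode of Hypergeom(40, 20, 10)/2-ish
        p, _, overlap = fisher_enrichment(module, gset, universe)
        assert p >= 0.5

    def test_matches_exhaustive_tail_oracle(self, rng):
        for _ in range(60):
            universe_size = int(rng.integers(10, 40))
            module_size = int(rng.integers(1, universe_size))
            set_size = int(rng.integers(1, universe_size))
            universe = [f"g{i}" for i in range(universe_size)]
            module = list(rng.choice(universe, size=module_size, replace=False))
            gset = list(rng.choice(universe, size=set_size, replace=False))
            p, _, overlap = fisher_enrichment(module, gset, universe)
            oracle = hypergeom_tail_oracle(overlap, module_size, set_size, universe_size)
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_monotone_in_overlap(self):
        # at fixed marginals, larger overlap never increases the one-sided p
        from gcnrefine.evaluate import _fisher_one_sided

        prev = 1.1
        for overlap in range(0, 11):
            p = _fisher_one_sided(overlap, 10, 15, 50)
            assert p <= prev + 1e-15
            prev = p

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment(["x"], ["g1"], ["g1", "g2"])

    def test_batch_adjustment_is_bh(self, rng):
        genes = [f"g{i}" for i in range(60)]
        part = Partition(genes, [1] * 30 + [2] * 30)
        coll = GeneSetCollection(
            {
                "S1": ("d", frozenset(genes[:25])),
                "S2": ("d", frozenset(genes[30:50])),
                "S3": ("d", frozenset(rng.choice(genes, size=10, replace=False))),
            }
        )
        results = enrichment_table(part, coll)
        assert len(results) == 6
        raw = np.array([r.p_value for r in results])
        adj = np.array([r.adjusted_p for r in results])
        from scipy.stats import false_discovery_control

        np.testing.assert_allclose(adj, np.minimum(false_discovery_control(raw, method="bh"), 1.0))
        for r in results:
            assert r.overlap <= min(r.module_size, r.set_size)
            assert 0 < r.p_value <= 1


def _res(module, p, adj):
    return EnrichmentResult(module, f"s{p}", 1, 10, 10, 100, p, adj, 1.0)


class TestSGo:
    def test_two_significant_terms_sum_logs(self):
        results = [_res(1, 1e-2, 1e-3), _res(1, 1e-3, 1e-4)]
        report = s_go(results)
        assert report.per_module[1] == pytest.approx(5.0)
        assert report.total == pytest.approx(5.0)

    def test_no_significant_results_zero(self):
        report = s_go([_res(1, 0.5, 0.9), _res(2, 0.2, 0.6)])
        assert report.total == 0.0
        assert report.n_significant == 0

    def test_additive_across_modules(self):
        results = [_res(1, 1e-5, 1e-4), _res(2, 1e-7, 1e-6)]
        report = s_go(results)
        assert report.total == pytest.approx(
            report.per_module[1] + report.per_module[2]
        )
        assert report.per_module[1] == pytest.approx(5.0)
        assert report.per_module[2] == pytest.approx(7.0)

    def test_gate_on_raw_switch(self):
        results = [_res(1, 1e-3, 0.2)]  # raw significant, adjusted not
        assert s_go(results).total == 0.0
        assert s_go(results, gate_on="raw").total == pytest.approx(3.0)


class TestRelativeImprovement:
    def test_fifteen_percent(self):
        after = s_go([_res(1, 1e-115, 1e-116)])
        before = s_go([_res(1, 1e-100, 1e-101)])
        assert relative_improvement(after, before) == pytest.approx(0.15)

    def test_identical_is_zero(self):
        r = s_go([_res(1, 1e-5, 1e-5)])
        assert relative_improvement(r, r) == 0.0

    def test_zero_baseline_rejected(self):
        nothing = s_go([])
        with pytest.raises(DegenerateDataError):
            relative_improvement(nothing, nothing)


class TestInformationContent:
    def test_certain_term_zero(self):
        assert information_content("t", {"t": 1.0}) == 0.0

    def test_log_identity(self):
        assert information_content("t", {"t": math.exp(-2)}) == pytest.approx(2.0)

    def test_base_switch(self):
        assert information_content("t", {"t": 0.01}, base="10") == pytest.approx(2.0)

    def test_zero_probability_rejected(self):
        with pytest.raises(ValidationError):
            information_content("t", {"t": 0.0})

    def test_absent_term_rejected(self):
        with pytest.raises(ValidationError):
            information_content("missing", {"t": 0.5})


class TestRandomReassignmentNull:
    def _pair(self, rng, n=40, k=4):
        genes = [f"g{i}" for i in range(n)]
        seed = random_partition(genes, k, rng, allow_unassigned=False)
        refined = seed.with_labels(seed.labels.copy())
        movers = rng.choice(n, size=10, replace=False)
        labels = refined.labels.copy()
        for g in movers:
            labels[g] = 1 + (labels[g]) % k
        return seed, seed.with_labels(labels)

    def test_no_movers_returns_refined(self, rng):
        genes = [f"g{i}" for i in range(10)]
        p = random_partition(genes, 3, rng)
        assert random_reassignment_null(p, p, 0) == p

    def test_size_multiset_and_fixed_set_preserved(self, rng):
        for draw in range(10):
            seed, refined = self._pair(rng)
            null = random_reassignment_null(seed, refined, draw)
            assert sorted(null.module_sizes().values()) == sorted(
                refined.module_sizes().values()
            )
            unchanged = seed.labels == refined.labels
            np.testing.assert_array_equal(
                null.labels[unchanged], seed.labels[unchanged]
            )

    def test_deterministic_given_seed(self, rng):
        seed, refined = self._pair(rng)
        a = random_reassignment_null(seed, refined, 99)
        b = random_reassignment_null(seed, refined, 99)
        assert a == b

    def test_different_seeds_usually_differ(self, rng):
        seed, refined = self._pair(rng)
        draws = {
            tuple(random_reassignment_null(seed, refined, s).labels.tolist())
            for s in range(10)
        }
        assert len(draws) > 1

    def test_universe_mismatch_rejected(self, rng):
        p = Partition(["a", "b"], [1, 2])
        q = Partition(["a", "c"], [1, 2])
        with pytest.raises(ValidationError):
            random_reassignment_null(p, q, 0)


class TestMoverMMStats:
    def test_no_movers_sentinel(self, two_block):
        ds, _ = two_block
        stats = mover_mm_stats(ds.expression, ds.truth, ds.truth)
        assert stats.empty and stats.n_movers == 0
        assert math.isnan(stats.departure_mean)

    def test_single_mover_matches_direct_correlations(self, rng):
        # 6-sample fixture with one gene moved between two 3-gene modules
        a = rng.standard_normal(6)
        b = rng.standard_normal(6)
        cols = [
            a + 0.1 * rng.standard_normal(6),
            a + 0.1 * rng.standard_normal(6),
            a + 0.1 * rng.standard_normal(6),
            b + 0.1 * rng.standard_normal(6),
            b + 0.1 * rng.standard_normal(6),
            0.5 * a + 0.5 * b,
        ]
        expr = ExpressionMatrix(
            np.column_stack(cols), [f"s{i}" for i in range(6)],
            [f"g{j}" for j in range(6)],
        )
        seed = Partition(expr.gene_ids, [1, 1, 1, 2, 2, 1])
        refined = Partition(expr.gene_ids, [1, 1, 1, 2, 2, 2])
        stats = mover_mm_stats(expr, seed, refined)
        assert stats.n_movers == 1
        seed_eg = module_eigengenes(expr, seed)
        dep = float(np.corrcoef(expr.values[:, 5], seed_eg.vectors[1])[0, 1])
        ref_eg = module_eigengenes(expr, refined)
        arr = float(np.corrcoef(expr.values[:, 5], ref_eg.vectors[2])[0, 1])
        assert stats.departure_mean == pytest.approx(dep, abs=1e-10)
        assert stats.arrival_mean == pytest.approx(arr, abs=1e-10)
        assert stats.departure_sd == 0.0 and stats.arrival_sd == 0.0

    def test_means_within_correlation_bounds(self, five_module_scrambled):
        ds, seed = five_module_scrambled
        from gcnrefine import refine

        final, _ = refine(ds.expression, seed)
        stats = mover_mm_stats(ds.expression, seed, final)
        assert stats.n_movers > 0
        for v in (stats.departure_mean, stats.arrival_mean):
            assert -1.0 <= v <= 1.0
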