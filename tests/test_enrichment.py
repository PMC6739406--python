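"""Hypergeometric over-representation, BH adjustment and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xcimir.enrichment import (
    bh_adjust,
    get_targets,
    hypergeom_enrich,
    hypergeom_pvalue,
    prioritize,
)
from xcimir import io as xio
from xcimir.models import DataError, GeneSet, GenomicFeature, HostingPair, Kind
from xcimir.synth import APOPTOSIS_GENES, gen_planted_enrichment

from .oracles import hypergeom_tail_by_counting, hypergeom_tail_by_enumeration


class TestHypergeomPvalue:
    def test_equals_subset_enumeration_on_the_worked_example(self):
        # N=20, K=5, n=5, k>=3: 1126 of the 15504 possible draws
        expected = hypergeom_tail_by_enumeration(3, 5, 5, 20)
        assert expected == pytest.approx(1126 / 15504)
        assert hypergeom_pvalue(3, 5, 5, 20) == pytest.approx(expected, abs=1e-12)

    def test_equals_counting_oracle_for_all_small_problems(self):
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                            hypergeom_tail_by_counting(k, K, n, N), abs=1e-10
                        )

    def test_null_type_one_error_calibration(self):
        # discrete p-values: sizes chosen so attained levels approximate
        # nominal ones; the analytic attained level here is 0.0378
        rng = np.random.default_rng(123)
        N, K, n = 2000, 200, 150
        names = [f"g{i}" for i in range(N)]
        background = set(names)
        geneset = GeneSet("S", frozenset(names[:K]))
        hits = 0
        reps = 2000
        for _ in range(reps):
            query = set(rng.choice(names, size=n, replace=False))
            (res,) = hypergeom_enrich(query, [geneset], background)
            hits += res.p_value <= 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestHypergeomEnrich:
    def test_planted_overlap_reproduces_analytic_p(self):
        background, geneset, query = gen_planted_enrichment(20, 5, 5, 3, seed=5)
        (res,) = hypergeom_enrich(query, [geneset], background)
        assert (res.k, res.K, res.n, res.N) == (3, 5, 5, 20)
        assert res.p_value == pytest.approx(1126 / 15504, abs=1e-12)

    def test_empty_set_overlap_gives_p_one(self):
        bg = {"A", "B", "C", "D"}
        (res,) = hypergeom_enrich({"A"}, [GeneSet("S", frozenset({"Z"}))], bg)
        assert (res.k, res.K, res.p_value) == (0, 0, 1.0)

    def test_query_equal_to_background_forces_p_one(self):
        bg = {"A", "B", "C", "D"}
        (res,) = hypergeom_enrich(bg, [GeneSet("S", frozenset({"A", "B"}))], bg)
        assert res.k == res.K and res.p_value == pytest.approx(1.0)

    def test_query_outside_background_is_an_error(self):
        with pytest.raises(DataError, match="STRAY"):
            hypergeom_enrich({"STRAY"}, [GeneSet("S", frozenset({"A"}))], {"A"})

    def test_empty_background_is_an_error(self):
        with pytest.raises(DataError):
            hypergeom_enrich(set(), [GeneSet("S", frozenset({"A"}))], set())

    def test_results_sorted_by_p_then_name(self):
        bg = {f"g{i}" for i in range(30)}
        sets = [
            GeneSet("B_NULL", frozenset(list(bg)[:3])),
            GeneSet("A_HIT", frozenset({"g0", "g1", "g2", "g3", "g4"})),
        ]
        res = hypergeom_enrich({"g0", "g1", "g2"}, sets, bg)
        assert res[0].p_value <= res[1].p_value


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_computed_step_up(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 then right-to-left minimum
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_inputs_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                bh_adjust([bad])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20))
    def test_rank_monotone_and_permutation_invariant(self, ps):
        adj = bh_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1 for a in adj)
        # sorted inputs give sorted outputs
        order = np.argsort(ps)
        adj_sorted = bh_adjust(sorted(ps))
        assert adj_sorted == sorted(adj_sorted)
        # adjusting a permutation permutes the adjustment
        assert np.allclose(np.array(adj)[order], adj_sorted)


class TestGetTargets:
    def test_fixture_target_sets(self, fixture_dir):
        interactions = xio.read_targets(fixture_dir / "targets.tsv")
        t548 = get_targets("hsa-miR-548am-5p", interactions)
        assert len(t548) == 332
        assert set(APOPTOSIS_GENES) <= t548
        assert len(get_targets("hsa-miR-4767", interactions)) == 3

    def test_arm_identifiers_match_exactly(self, fixture_dir):
        interactions = xio.read_targets(fixture_dir / "targets.tsv")
        assert get_targets("hsa-miR-548am-3p", interactions) == set()
        assert get_targets("hsa-miR-548am", interactions) == set()

    def test_unknown_mir_is_empty(self):
        assert get_targets("hsa-miR-0", []) == set()


def _pair(gene_id):
    g = GenomicFeature(gene_id, Kind.GENE, "chrX", 0, 1000)
    m = GenomicFeature("m", Kind.MIRNA, "chrX", 10, 90)
    return HostingPair(gene=g, mir=m)


def _enrich(name, p_adj):
    from xcimir.models import EnrichmentResult

    return EnrichmentResult(set_name=name, k=1, K=5, n=5, N=50, p_value=min(p_adj, 1.0),
                            p_adjusted=p_adj)


class TestPrioritize:
    def test_supported_enriched_many_target_mir_ranks_first(self):
        strong = ("miR-B", _pair("CTPS2"), True, set(map(str, range(332))),
                  [_enrich("APOPTOSIS", 0.013)])
        weak = ("miR-A", _pair("PUDP"), True, {"x", "y", "z"}, [])
        ranking = prioritize([weak, strong], "APOPTOSIS")
        assert [r.mir_id for r in ranking] == ["miR-B", "miR-A"]
        assert [r.rank for r in ranking] == [1, 2]

    def test_single_candidate_gets_rank_one(self):
        (r,) = prioritize([("m", _pair("G"), False, set(), [])], "APOPTOSIS")
        assert r.rank == 1

    def test_identical_candidates_break_ties_lexicographically(self):
        a = ("miR-a", _pair("G"), True, {"x"}, [])
        b = ("miR-b", _pair("G"), True, {"y"}, [])
        ranking = prioritize([b, a], "APOPTOSIS")
        assert [r.mir_id for r in ranking] == ["miR-a", "miR-b"]

    def test_empty_candidates_empty_ranking(self):
        assert prioritize([], "APOPTOSIS") == []
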