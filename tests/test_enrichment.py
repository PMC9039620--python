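import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import exact_tail, exact_tail_suffix
from pagkit.enrichment import (
    EnrichmentResult,
    GeneSetOverlap,
    adjust_pvalues,
    enrich,
    hypergeom_tail_suffix,
    hypergeom_upper_tail,
    similarity_score,
)
from pagkit.errors import ArgumentError
from pagkit.io_formats import PAG


def _overlap(k, cand, pag, universe=1000):
    genes = frozenset(f"G{i}" for i in range(k))
    return GeneSetOverlap(
        pag_id="X",
        universe_size=universe,
        candidate_size=cand,
        pag_size=pag,
        overlap_genes=genes,
    )


class TestHypergeomUpperTail:
    def test_zero_overlap_is_one(self):
        assert hypergeom_upper_tail(100, 10, 10, 0) == 1.0

    def test_full_overlap_exact(self):
        # all 5 candidates inside a 5-gene set: a single draw out of C(20,5)
        expected = 1 / math.comb(20, 5)
        assert hypergeom_upper_tail(20, 5, 5, 5) == pytest.approx(expected, rel=1e-12)

    @given(
        N=st.integers(1, 50),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_summation(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        got = hypergeom_upper_tail(N, K, n, k)
        expected = float(exact_tail(N, K, n, k))
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_suffix_vector_matches_scalar(self):
        tails = hypergeom_tail_suffix(60, 25, 30)
        oracle = exact_tail_suffix(60, 25, 30)
        assert tails == pytest.approx(oracle, rel=1e-12)

    def test_non_increasing_in_overlap(self):
        tails = hypergeom_tail_suffix(200, 40, 50)
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ArgumentError):
            hypergeom_upper_tail(10, 20, 5, 2)
        with pytest.raises(ArgumentError):
            hypergeom_upper_tail(10, 5, 5, 6)


class TestSimilarityScore:
    def test_identical_sets(self):
        assert similarity_score(_overlap(5, 5, 5)) == 1.0

    def test_disjoint_sets(self):
        assert similarity_score(_overlap(0, 4, 8)) == 0.0

    def test_hand_arithmetic(self):
        # OC = 4/4 = 1, J = 4/(4+8-4) = 0.5, mean = 0.75
        assert similarity_score(_overlap(4, 4, 8)) == pytest.approx(0.75)

    def test_combiners(self):
        ov = _overlap(4, 4, 8)
        assert similarity_score(ov, "min") == pytest.approx(0.5)
        assert similarity_score(ov, "max") == pytest.approx(1.0)
        with pytest.raises(ArgumentError):
            similarity_score(ov, "geometric")

    def test_zero_sized_sets(self):
        with pytest.raises(ArgumentError):
            similarity_score(_overlap(0, 0, 5))

    @given(
        cand=st.integers(1, 50),
        pag=st.integers(1, 50),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded(self, cand, pag, data):
        k = data.draw(st.integers(0, min(cand, pag)))
        s = similarity_score(_overlap(k, cand, pag))
        assert 0.0 <= s <= 1.0


class TestAdjustPvalues:
    def test_single_test_identity(self):
        assert adjust_pvalues([0.03]) == [0.03]

    def test_smallest_of_ten(self):
        # p0=0.01 smallest among 10 distinct: n_le=1, multiplier 10
        p = [0.01, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]
        adjusted = adjust_pvalues(p)
        assert adjusted[0] == pytest.approx(0.01 * (10 + 1 - 1))

    def test_largest_clamped(self):
        # p0=0.2 largest among 10: 0.2 * (10 + 10 - 1) = 3.8 -> clamp 1.0
        p = [0.2] + [0.01 * i for i in range(1, 10)]
        adjusted = adjust_pvalues(p)
        assert adjusted[0] == 1.0

    def test_order_preserved_and_ge_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1.0, size=40).tolist()
        adjusted = adjust_pvalues(p)
        assert len(adjusted) == 40
        for raw, adj in zip(p, adjusted):
            assert adj >= raw - 1e-15
            assert adj <= 1.0

    def test_ties_counted_inclusively(self):
        # three equal values: each has n_le = 3, multiplier m + 3 - 1
        adjusted = adjust_pvalues([0.1, 0.1, 0.1])
        assert adjusted == pytest.approx([0.1 * 5] * 3)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(1e-6, 1.0, size=25).tolist()
        adjusted = adjust_pvalues(p)
        m = len(p)
        for p0, adj in zip(p, adjusted):
            n_le = sum(1 for q in p if q <= p0)
            assert adj == pytest.approx(min(1.0, p0 * (m + n_le - 1)))

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            adjust_pvalues([])
        with pytest.raises(ArgumentError):
            adjust_pvalues([0.0])


def _toy_collection():
    """5 small PAGs over a 30-gene universe."""
    mk = lambda i, genes: PAG(
        pag_id=f"S{i}", name=f"S{i}", source="toy", genes=frozenset(genes)
    )
    g = [f"G{i:02d}" for i in range(30)]
    return [
        mk(1, g[0:5]),
        mk(2, g[3:10]),
        mk(3, g[10:20]),
        mk(4, g[15:25]),
        mk(5, g[20:30]),
    ]


class TestEnrich:
    def test_exact_pag_match_wins(self):
        pags = _toy_collection()
        candidates = set(pags[0].genes)
        results = enrich(candidates, pags, min_overlap=1, neg_log2p_cutoff=0.0)
        assert results[0].pag_id == "S1"
        assert results[0].similarity_score == 1.0
        assert all(results[0].p_raw <= r.p_raw for r in results)

    def test_min_overlap_filters_everything(self):
        pags = _toy_collection()
        results = enrich(set(pags[0].genes), pags, min_overlap=100)
        assert results == []

    def test_planted_fixture_ranks_first(self, bundle):
        results = enrich(set(bundle.manifest["candidates"]), bundle.pags)
        top = {r.pag_id for r in results[: len(bundle.manifest["enriched_pags"])]}
        assert top == set(bundle.manifest["enriched_pags"])

    def test_m_is_survivor_count(self):
        # adding a PAG that fails the overlap filter must not change any
        # adjusted p-value of the survivors
        pags = _toy_collection()
        candidates = set(pags[0].genes) | set(list(pags[2].genes)[:3])
        base = enrich(candidates, pags, min_overlap=3, neg_log2p_cutoff=0.0)
        extra = PAG(
            pag_id="S9", name="S9", source="toy",
            genes=frozenset(set(list(pags[4].genes)[:4]) | {"G29"}),
        )
        with_extra = enrich(
            candidates, pags + [extra], min_overlap=3, neg_log2p_cutoff=0.0
        )
        surviving = {r.pag_id for r in with_extra}
        assert "S9" not in surviving
        base_map = {r.pag_id: r.p_adjusted for r in base}
        for r in with_extra:
            assert r.p_adjusted == pytest.approx(base_map[r.pag_id])

    def test_input_order_invariance(self):
        pags = _toy_collection()
        candidates = set(pags[0].genes) | set(list(pags[2].genes)[:4])
        a = enrich(candidates, pags, min_overlap=1, neg_log2p_cutoff=0.0)
        b = enrich(candidates, pags[::-1], min_overlap=1, neg_log2p_cutoff=0.0)
        assert [(r.pag_id, r.p_adjusted) for r in a] == [
            (r.pag_id, r.p_adjusted) for r in b
        ]

    def test_sorted_by_adjusted_p_then_id(self):
        pags = _toy_collection()
        candidates = set(pags[0].genes) | set(pags[2].genes)
        results = enrich(candidates, pags, min_overlap=1, neg_log2p_cutoff=0.0)
        keys = [(r.p_adjusted, r.pag_id) for r in results]
        assert keys == sorted(keys)

    def test_candidates_outside_universe_rejected(self):
        pags = _toy_collection()
        with pytest.raises(ArgumentError):
            enrich({"NOT_A_GENE"}, pags)

    def test_neg_log2_p_field(self):
        pags = _toy_collection()
        results = enrich(
            set(pags[0].genes), pags, min_overlap=1, neg_log2p_cutoff=0.0
        )
        for r in results:
            assert r.neg_log2_p == pytest.approx(-math.log2(r.p_adjusted))
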