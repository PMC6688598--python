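"""Scoring primitives: Jaccard, sub-pathway enumeration, overlap p-values."""

import itertools
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from rspnet.core import (
    PairOverlap,
    Rsp,
    assign_pathways,
    enumerate_rsps,
    hop_overlap,
    jaccard,
    js_score,
    pair_pvalue,
    pair_pvalue_exact,
    score_rsp,
)
from rspnet.io import AnnotationCatalog, InteractionGraph

TERMS = st.sets(st.sampled_from("abcdefgh"), max_size=8)


def catalog(ns, **term_sets):
    return AnnotationCatalog.from_term_sets(ns, term_sets)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),  # the worked example
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            (set(), set(), 0.0),  # 0/0 convention: non-viable
            (set(), {"a"}, 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard(a, b) == expected

    @given(TERMS, TERMS)
    def test_symmetric_and_bounded(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0


class TestEnumerate:
    def test_star_graph_yields_two_hop_paths_only(self):
        g = InteractionGraph.from_pairs([("T", "A"), ("A", "B"), ("A", "C")])
        assert enumerate_rsps("T", g) == [Rsp("T", "A", "B"), Rsp("T", "A", "C")]

    def test_triangle_excludes_backtracking_to_target(self):
        g = InteractionGraph.from_pairs([("T", "A"), ("A", "B"), ("B", "T")])
        assert enumerate_rsps("T", g) == [Rsp("T", "A", "B"), Rsp("T", "B", "A")]

    def test_backtracking_admitted_when_allowed(self):
        g = InteractionGraph.from_pairs([("T", "A"), ("A", "B")])
        got = enumerate_rsps("T", g, allow_backtrack=True)
        assert Rsp("T", "A", "T") in got

    def test_absent_target_yields_empty_list(self):
        g = InteractionGraph.from_pairs([("A", "B")])
        assert enumerate_rsps("X", g) == []

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_triple_loop_on_random_graphs(self, seed):
        import random

        rnd = random.Random(seed)
        n = rnd.randint(3, 15)
        nodes = [f"N{i}" for i in range(n)]
        pairs = [
            (a, b)
            for a, b in itertools.combinations(nodes, 2)
            if rnd.random() < 0.3
        ]
        g = InteractionGraph.from_pairs(pairs)
        target = nodes[0]
        oracle = sorted(
            Rsp(t, g1, g2)
            for t, g1, g2 in itertools.product(nodes, repeat=3)
            if t == target
            and len({t, g1, g2}) == 3
            and g.has_edge(t, g1)
            and g.has_edge(g1, g2)
        )
        assert sorted(enumerate_rsps(target, g)) == oracle


class TestJsScore:
    def test_chained_overlap_sets_score_half(self):
        cat = catalog("BP", T={"a", "b", "c"}, G1={"b", "c", "d"}, G2={"c", "d", "e"})
        score, viable = js_score(Rsp("T", "G1", "G2"), cat)
        assert score == 0.5 and viable

    def test_identical_sets_score_one(self):
        cat = catalog("BP", T={"a", "b"}, G1={"a", "b"}, G2={"a", "b"})
        assert js_score(Rsp("T", "G1", "G2"), cat) == (1.0, True)

    def test_disjoint_first_hop_is_not_viable(self):
        cat = catalog("BP", T={"a"}, G1={"b"}, G2={"b"})
        score, viable = js_score(Rsp("T", "G1", "G2"), cat)
        # second hop is identical sets (JC = 1) but the zero first hop
        # makes the path non-viable regardless
        assert not viable and score == 0.5


def feasible_configs(max_n):
    for N in range(1, max_n + 1):
        for x in range(N + 1):
            for y in range(N + 1):
                for n1 in range(max(0, x + y - N), min(x, y) + 1):
                    yield x, y, n1, N


class TestPairPvalue:
    @pytest.mark.parametrize(
        "x, y, n, N, expected",
        [
            (4, 2, 2, 4, 1.0),  # first set is the whole universe
            (2, 2, 2, 4, Fraction(1, 6)),
            (3, 2, 1, 5, Fraction(6, 10)),
        ],
    )
    def test_known_values(self, x, y, n, N, expected):
        assert pair_pvalue_exact(PairOverlap(x, y, n, N)) == expected

    def test_infeasible_overlap_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="infeasible"):
            pair_pvalue(PairOverlap(2, 2, 3, 4))
        with pytest.raises(ValueError, match="infeasible"):
            pair_pvalue(PairOverlap(3, 3, 0, 4))  # shared below feasibility floor

    def test_pmf_normalizes_exactly(self):
        for N in range(1, 10):
            for x in range(N + 1):
                for y in range(N + 1):
                    total = sum(
                        pair_pvalue_exact(PairOverlap(x, y, n, N))
                        for n in range(max(0, x + y - N), min(x, y) + 1)
                    )
                    assert total == 1

    def test_matches_scipy_hypergeometric_point_mass(self):
        for x, y, n, N in feasible_configs(9):
            ours = pair_pvalue(PairOverlap(x, y, n, N))
            ref = hypergeom.pmf(n, N, x, y)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_literal_triple_binomial_formula_agrees(self):
        # C(N,n) C(N-n, x-n) C(N-x, y-n) / (C(N,x) C(N,y)), exactly
        for x, y, n, N in feasible_configs(9):
            literal = Fraction(
                comb(N, n) * comb(N - n, x - n) * comb(N - x, y - n),
                comb(N, x) * comb(N, y),
            )
            assert pair_pvalue_exact(PairOverlap(x, y, n, N)) == literal

    def test_matches_subset_enumeration(self):
        universe = list(range(6))
        for x in range(7):
            fixed = set(universe[:x])
            for y in range(7):
                counts = {}
                for sub in itertools.combinations(universe, y):
                    k = len(fixed & set(sub))
                    counts[k] = counts.get(k, 0) + 1
                total = comb(6, y)
                for n, c in counts.items():
                    assert pair_pvalue_exact(
                        PairOverlap(x, y, n, 6)
                    ) == Fraction(c, total)

    def test_tail_mode_sums_upper_tail(self):
        ov = PairOverlap(3, 3, 1, 8)
        tail = pair_pvalue_exact(ov, tail=True)
        point = sum(
            pair_pvalue_exact(PairOverlap(3, 3, k, 8)) for k in (1, 2, 3)
        )
        assert tail == point


class TestScoreRsp:
    BP = {"T": {"a", "b", "c"}, "G1": {"b", "c", "d"}, "G2": {"c", "d", "e"},
          "U1": {"f"}, "U2": {"g"}, "U3": {"h"}}

    def bp_catalog(self):
        return catalog("BP", **self.BP)

    def test_p_value_is_max_of_hand_computed_hop_pvalues(self):
        cat = self.bp_catalog()
        rsp = Rsp("T", "G1", "G2")
        rec = score_rsp(rsp, cat, cat, "BP")
        p1 = pair_pvalue(hop_overlap("T", "G1", cat))
        p2 = pair_pvalue(hop_overlap("G1", "G2", cat))
        assert rec.p1 == p1 and rec.p2 == p2
        assert rec.p_value == max(p1, p2)

    def test_symmetric_hops_give_equal_pvalues(self):
        cat = self.bp_catalog()
        rec = score_rsp(Rsp("T", "G1", "G2"), cat, cat, "BP")
        # x=y=z=3 and n1=n2=2: the two hop p-values coincide
        assert rec.p1 == rec.p2 == rec.p_value

    def test_zero_jaccard_hop_discards_in_selected_namespace(self):
        cat = self.bp_catalog()
        assert score_rsp(Rsp("U1", "U2", "U3"), cat, cat, "BP") is None

    def test_viability_gate_uses_selected_namespace_only(self):
        bp = self.bp_catalog()
        mf = catalog("MF", T={"x"}, G1={"y"}, G2={"z"})  # non-viable in MF
        rsp = Rsp("T", "G1", "G2")
        assert score_rsp(rsp, bp, mf, "MF") is None
        rec = score_rsp(rsp, bp, mf, "BP")
        assert rec is not None and rec.viable_bp and not rec.viable_mf

    def test_pathway_namespace_rejected_for_scoring(self):
        cat = self.bp_catalog()
        with pytest.raises(ValueError):
            score_rsp(Rsp("T", "G1", "G2"), cat, cat, "PATHWAY")


class TestAssignPathways:
    CAT = AnnotationCatalog.from_term_sets(
        "PATHWAY",
        {"T": {"PW1", "PW2"}, "G1": {"PW1", "PW2"}, "G2": {"PW1"}, "X": {"PW3"}},
    )

    def test_all_three_rule(self):
        assert assign_pathways(Rsp("T", "G1", "G2"), self.CAT) == {"PW1"}

    def test_partial_membership_excluded(self):
        assert assign_pathways(Rsp("T", "G1", "X"), self.CAT) == frozenset()

    def test_any_gene_mode(self):
        got = assign_pathways(Rsp("T", "G1", "X"), self.CAT, require_all=False)
        assert got == {"PW1", "PW2", "PW3"}
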