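"""Conflict sets, essential edges and minimal chain cover enumeration."""

import itertools

import pytest

from chaincover import (
    BipartiteGraph,
    build_conflict_index,
    conflict_set,
    enumerate_essential_chain_subgraphs,
    enumerate_maximal_chain_subgraphs,
    enumerate_minimal_covers,
    enumerate_minimal_set_covers,
    essential_edges,
    minimum_cover_size,
    max_induced_matching_size,
)
from conftest import brute_minimal_covers


class TestConflictSets:
    def test_2k2_defining_pattern(self, two_k2):
        assert conflict_set(two_k2, ("u1", "w1")) == {("u2", "w2")}

    def test_chain_graph_conflicts_empty(self, fig2):
        _, G, _ = fig2
        assert all(conflict_set(G, e) == frozenset() for e in G.edges)

    def test_antimatching_singletons(self, a6):
        assert conflict_set(a6, ("u1", "w2")) == {("u2", "w1")}

    def test_rejects_non_edge(self, a6):
        with pytest.raises(ValueError):
            conflict_set(a6, ("u1", "w1"))

    def test_symmetry_on_corpus(self, corpus):
        for G in corpus[:40]:
            conflicts = {e: conflict_set(G, e) for e in G.edges}
            for e, Me in conflicts.items():
                for e2 in Me:
                    assert e in conflicts[e2]


class TestEssentialEdges:
    def test_chain_graph_all_essential(self, fig2):
        _, G, _ = fig2
        assert essential_edges(G) == G.edges

    def test_p5_endpoints_only(self, p5):
        assert essential_edges(p5) == {("u1", "w1"), ("u3", "w2")}

    def test_antimatching_all_essential(self, a6):
        assert essential_edges(a6) == a6.edges

    def test_conflict_chain_duality_on_corpus(self, corpus_brute):
        """C_e is contained in C_e' exactly when M_e contains M_e'."""
        for G, brute in corpus_brute:
            index = build_conflict_index(G)
            through = {e: frozenset(C for C in brute if e in C) for e in G.edges}
            for e1, e2 in itertools.permutations(G.edges, 2):
                assert (through[e1] <= through[e2]) == (
                    index.conflicts[e1] >= index.conflicts[e2]
                )

    def test_essential_matches_definition_on_corpus(self, corpus_brute):
        """The conflict-set shortcut must reproduce the defining property:
        e is non-essential iff some C_e' is strictly inside C_e."""
        for G, brute in corpus_brute[:60]:
            through = {e: frozenset(C for C in brute if e in C) for e in G.edges}
            by_definition = frozenset(
                e
                for e in G.edges
                if not any(through[e2] < through[e] for e2 in G.edges)
            )
            assert essential_edges(G) == by_definition


class TestEssentialChainEnumeration:
    def test_p5_both_chains_qualify(self, p5):
        assert {C.edges for C in enumerate_essential_chain_subgraphs(p5)} == {
            C.edges for C in enumerate_maximal_chain_subgraphs(p5)
        }

    def test_2k2_both_single_edges(self, two_k2):
        assert {C.edges for C in enumerate_essential_chain_subgraphs(two_k2)} == {
            frozenset({("u1", "w1")}),
            frozenset({("u2", "w2")}),
        }

    def test_filters_to_chains_meeting_essential_edges(self, corpus):
        for G in corpus[:40]:
            ess = essential_edges(G)
            expected = {
                C.edges
                for C in enumerate_maximal_chain_subgraphs(G)
                if C.edges & ess
            }
            got = {C.edges for C in enumerate_essential_chain_subgraphs(G)}
            assert got == expected

    def test_membership_shortcut(self, corpus):
        """If a maximal chain avoids all of M_e then it contains e."""
        for G in corpus[:30]:
            index = build_conflict_index(G)
            for C in enumerate_maximal_chain_subgraphs(G):
                for e, Me in index.conflicts.items():
                    if not C.edges & Me:
                        assert e in C.edges


class TestMinimalSetCovers:
    def test_three_member_family(self):
        ground = frozenset({1, 2})
        family = [frozenset({1}), frozenset({2}), frozenset({1, 2})]
        covers = set(enumerate_minimal_set_covers(ground, family))
        assert covers == {frozenset({0, 1}), frozenset({2})}

    def test_singleton(self):
        assert list(enumerate_minimal_set_covers(frozenset({1}), [frozenset({1})])) == [
            frozenset({0})
        ]

    def test_uncoverable_element_raises(self):
        with pytest.raises(ValueError, match="2"):
            list(enumerate_minimal_set_covers(frozenset({1, 2}), [frozenset({1})]))

    def test_matches_exhaustive_search_on_random_instances(self):
        import numpy as np

        rng = np.random.default_rng(11)
        for _ in range(40):
            ground = frozenset(range(int(rng.integers(1, 6))))
            family = [
                frozenset(x for x in ground if rng.random() < 0.5)
                for _ in range(int(rng.integers(1, 6)))
            ]
            if not frozenset().union(*family) == ground:
                continue
            expected = set()
            for r in range(1, len(family) + 1):
                for combo in itertools.combinations(range(len(family)), r):
                    if frozenset().union(*(family[i] for i in combo)) == ground:
                        expected.add(frozenset(combo))
            expected = {
                c for c in expected if not any(o < c for o in expected)
            }
            got = set(enumerate_minimal_set_covers(ground, family))
            assert got == expected


class TestMinimalCoverEnumeration:
    def test_chain_graph_single_cover(self, fig2):
        _, G, _ = fig2
        covers = list(enumerate_minimal_covers(G))
        assert len(covers) == 1
        assert covers[0].chain_edge_sets() == {G.edges}

    def test_p5_unique_cover_of_both_chains(self, p5):
        covers = list(enumerate_minimal_covers(p5))
        assert len(covers) == 1
        assert covers[0].size == 2

    def test_edgeless_graph_yields_single_empty_cover(self):
        G = BipartiteGraph(["u1"], ["w1"], [])
        covers = list(enumerate_minimal_covers(G))
        assert len(covers) == 1 and covers[0].size == 0

    def test_antimatching_size_two_covers_pair_reversed_permutations(self, a6):
        """A size-2 cover of A_6 must pair a permutation chain with its
        reversal; there are exactly 3 such pairs."""
        size2 = [c for c in enumerate_minimal_covers(a6) if c.size == 2]
        assert len(size2) == 3
        for cover in size2:
            c1, c2 = cover.chains
            # reversal pairing: the two chains partition the 6 edges
            assert c1.edges | c2.edges == a6.edges
            assert c1.edges & c2.edges == frozenset()

    def test_matches_brute_force_on_corpus(self, corpus_brute):
        for G, brute in corpus_brute[:60]:
            if len(brute) > 14:
                continue
            expected = brute_minimal_covers(G, brute)
            got = {c.chain_edge_sets() for c in enumerate_minimal_covers(G)}
            assert got == expected

    def test_minimum_over_stream_equals_minimum_cover_size(self, corpus):
        for G in corpus[:40]:
            sizes = [c.size for c in enumerate_minimal_covers(G)]
            assert min(sizes) == minimum_cover_size(G)
            assert min(sizes) >= max_induced_matching_size(G)

    def test_chains_in_some_minimal_cover_iff_essential_edge(self, corpus_brute):
        for G, brute in corpus_brute[:60]:
            if len(brute) > 14:
                continue
            ess = essential_edges(G)
            in_some_cover = frozenset().union(*brute_minimal_covers(G, brute)) \
                if brute_minimal_covers(G, brute) else frozenset()
            for C in brute:
                assert (C in in_some_cover) == bool(C & ess)
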