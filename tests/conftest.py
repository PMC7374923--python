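"""Shared fixtures: named small graphs and the seeded random-graph corpus."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from chaincover import (
    BipartiteGraph,
    antimatching,
    brute_force_maximal_chain_subgraphs,
    fig2_fixture,
    random_bipartite,
)


@pytest.fixture(scope="session")
def fig2():
    matrix, G, lk = fig2_fixture()
    return matrix, G, lk


@pytest.fixture(scope="session")
def two_k2() -> BipartiteGraph:
    return BipartiteGraph(
        ["u1", "u2"], ["w1", "w2"], [("u1", "w1"), ("u2", "w2")]
    )


@pytest.fixture(scope="session")
def p5() -> BipartiteGraph:
    """The 5-node path u1-w1-u2-w2-u3."""
    return BipartiteGraph(
        ["u1", "u2", "u3"],
        ["w1", "w2"],
        [("u1", "w1"), ("u2", "w1"), ("u2", "w2"), ("u3", "w2")],
    )


@pytest.fixture(scope="session")
def a6() -> BipartiteGraph:
    return antimatching(6)


CORPUS_SIZE = 200
CORPUS_EDGE_CAP = 12  # keeps the exhaustive oracles within budget


def _make_corpus(size: int) -> list[BipartiteGraph]:
    """Seeded random bipartite graphs with sides <= 5, small enough for the
    brute-force oracles (m <= CORPUS_EDGE_CAP), at least one edge."""
    graphs = []
    seed = 0
    master = np.random.default_rng(20200722)
    while len(graphs) < size:
        n1 = int(master.integers(2, 6))
        n2 = int(master.integers(2, 6))
        p = float(master.uniform(0.3, 0.7))
        G = random_bipartite(n1, n2, p, seed)
        seed += 1
        if 1 <= G.m <= CORPUS_EDGE_CAP:
            graphs.append(G)
    return graphs


@pytest.fixture(scope="session")
def corpus() -> list[BipartiteGraph]:
    return _make_corpus(CORPUS_SIZE)


@pytest.fixture(scope="session")
def corpus_brute(corpus):
    """(graph, brute-force maximal chain edge sets) for the whole corpus."""
    return [(G, brute_force_maximal_chain_subgraphs(G)) for G in corpus]


def brute_minimal_covers(G: BipartiteGraph, chains) -> set[frozenset]:
    """Independent oracle: all minimal covers among subsets of the maximal
    chain subgraphs (exhaustive over 2^|chains| subsets)."""
    chains = sorted(chains, key=sorted)
    covers = []
    for r in range(1, len(chains) + 1):
        for combo in itertools.combinations(range(len(chains)), r):
            union = frozenset().union(*(chains[i] for i in combo))
            if union == G.edges:
                covers.append(frozenset(combo))
    minimal = {
        c
        for c in covers
        if not any(other < c for other in covers)
    }
    return {frozenset(chains[i] for i in c) for c in minimal}
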