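"""Synthetic incompatibility graphs and the worked-example fixture.

Three generators cover the regimes the algorithms are exercised on:

* :func:`antimatching` — the extremal family (complete bipartite minus a
  perfect matching) whose maximal chain subgraphs are exactly the (n/2)!
  permutations of one side;
* :func:`random_bipartite` — Erdos-Renyi-style bipartite graphs, seeded;
* :func:`planted_cover` — a union of k random chain graphs, guaranteeing a
  chain cover of size <= k by construction.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import BipartiteGraph, ChainSubgraph, IncompatibilityMatrix
from .lockkey import LockKeyPair

__all__ = [
    "antimatching",
    "random_bipartite",
    "random_chain_graph",
    "planted_cover",
    "fig2_fixture",
]


def _labels(prefix: str, count: int) -> list[str]:
    # zero-padded so lexicographic label order equals numeric order
    width = len(str(count))
    return [f"{prefix}{i:0{width}d}" for i in range(1, count + 1)]


def antimatching(n: int) -> BipartiteGraph:
    """A_n: complete bipartite graph on n/2 + n/2 nodes minus the perfect
    matching u_i w_i; requires even n >= 4.

    The extremal instance: exactly (n/2)! maximal chain subgraphs, one per
    permutation of U.
    """
    if n % 2 != 0 or n < 4:
        raise ValueError("antimatching requires an even n >= 4")
    half = n // 2
    U = _labels("u", half)
    W = _labels("w", half)
    edges = [(U[i], W[j]) for i in range(half) for j in range(half) if i != j]
    return BipartiteGraph(U, W, edges)


def random_bipartite(n1: int, n2: int, p: float, seed: int) -> BipartiteGraph:
    """Each of the n1*n2 potential edges present independently with
    probability p, under a seeded generator."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("edge probability p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    U = _labels("u", n1)
    W = _labels("w", n2)
    mask = rng.random((n1, n2)) < p
    edges = [(U[i], W[j]) for i in range(n1) for j in range(n2) if mask[i, j]]
    return BipartiteGraph(U, W, edges)


def random_chain_graph(n1: int, n2: int, rng: np.random.Generator) -> set[tuple[str, str]]:
    """Edge set of a random chain graph on the labelled sides.

    Draw a uniform permutation of the males and a monotone sequence of
    neighbourhood sizes, then take nested prefixes of a random permutation
    of the females.
    """
    U = _labels("u", n1)
    W = _labels("w", n2)
    male_order = rng.permutation(n1)
    female_order = rng.permutation(n2)
    sizes = np.sort(rng.integers(0, n2 + 1, size=n1))
    edges: set[tuple[str, str]] = set()
    for rank, mi in enumerate(male_order):
        for j in range(sizes[rank]):
            edges.add((U[mi], W[female_order[j]]))
    return edges


def planted_cover(
    n1: int, n2: int, k: int, seed: int
) -> tuple[BipartiteGraph, list[frozenset[tuple[str, str]]]]:
    """Union of k seeded random chain graphs; the planted chains witness a
    chain cover of size <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    planted = [frozenset(random_chain_graph(n1, n2, rng)) for _ in range(k)]
    edges: set[tuple[str, str]] = set()
    for ch in planted:
        edges |= ch
    G = BipartiteGraph(_labels("u", n1), _labels("w", n2), edges)
    return G, planted


def fig2_fixture() -> tuple[IncompatibilityMatrix, BipartiteGraph, LockKeyPair]:
    """The two-male, three-female worked example.

    M1 is incompatible with every female, M2 with F1 only.  The graph is a
    single chain, explainable by one Lock/Key molecule pair with
    L = (M1: 3, M2: 1) and K = (F1: 0, F2: 2, F3: 2).
    """
    df = pd.DataFrame(
        [[1, 1, 1], [1, 0, 0]], index=["M1", "M2"], columns=["F1", "F2", "F3"]
    )
    matrix = IncompatibilityMatrix(df)
    G = BipartiteGraph(
        ["M1", "M2"], ["F1", "F2", "F3"],
        [("M1", "F1"), ("M1", "F2"), ("M1", "F3"), ("M2", "F1")],
    )
    L = pd.DataFrame({"lock_1": [3, 1]}, index=["M1", "M2"])
    K = pd.DataFrame({"key_1": [0, 2, 2]}, index=["F1", "F2", "F3"])
    return matrix, G, LockKeyPair(L, K)
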