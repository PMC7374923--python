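"""Exact minimum chain-cover size by inclusion-exclusion.

The number ``c_k(G)`` of chain subgraph covers of size ``k`` (ordered
k-tuples, with repetition, of maximal chain subgraphs whose union is the
whole edge set) satisfies

    c_k(G) = sum over A subset of E of (-1)^|A| * a(A)^k

where ``a(A)`` counts the maximal chain subgraphs of ``G`` disjoint from
``A``.  The minimum chain cover size is the smallest ``k`` with
``c_k(G) != 0`` — and, by the Lock/Key correspondence, the minimum number of
Lock/Key molecule pairs explaining the incompatibility matrix.

All arithmetic is exact Python integers (``a(empty)^k`` overflows fixed
width already at desk scale); the 2^m outer sum is guarded by an edge-count
limit.  The ``a(.)`` table is obtained in one pass: the maximal chain
subgraphs are enumerated once as edge bitmasks and a subset-sum (zeta)
transform turns them into ``a(A)`` for every ``A`` simultaneously, instead
of re-enumerating per subset.  :func:`count_avoiding` keeps the direct
single-``A`` route (enumerate in the edge-deleted graph, filter by
maximality in the host) and the two routes are cross-checked in the tests.
"""

from __future__ import annotations

import itertools

import networkx as nx

from .graph import BipartiteGraph, Edge, is_chain_subset
from .enumerate_chains import enumerate_maximal_chain_subgraphs

__all__ = [
    "count_avoiding",
    "count_covers",
    "minimum_cover_size",
    "max_induced_matching",
    "max_induced_matching_size",
    "DEFAULT_EDGE_GUARD",
]

DEFAULT_EDGE_GUARD = 20


def _guard(m: int, max_edges: int, force: bool) -> None:
    if m > max_edges and not force:
        raise ValueError(
            f"refusing 2^{m}-term sum for m={m} > {max_edges} edges "
            "(raise max_edges or pass force=True)"
        )


def _is_maximal_in(G: BipartiteGraph, edge_set: frozenset[Edge]) -> bool:
    """Is the chain edge set maximal in ``G`` (no host edge addable)?"""
    return not any(is_chain_subset(edge_set | {e}) for e in G.edges - edge_set)


def count_avoiding(G: BipartiteGraph, A: frozenset[Edge] | set[Edge]) -> int:
    """a(A): the number of maximal chain subgraphs of ``G`` disjoint from ``A``.

    Computed directly: enumerate the maximal chain subgraphs of
    ``G' = (U + W, E \\ A)`` and keep those that are still maximal in ``G``.
    """
    A = frozenset(A)
    if not A <= G.edges:
        raise ValueError("A must be a subset of the edges of G")
    G_prime = BipartiteGraph(G.U, G.W, G.edges - A)
    return sum(
        1
        for C in enumerate_maximal_chain_subgraphs(G_prime)
        if _is_maximal_in(G, C.edges)
    )


def _avoiding_table(G: BipartiteGraph) -> list[int]:
    """a(A) for every A subset of E, indexed by edge bitmask.

    C is disjoint from A iff A is contained in the complement of C, so the
    table is the superset-indicator sum of the chain complements, computed
    with the standard subset-sum dynamic programme in O(2^m * m).
    """
    edges = G.sorted_edges()
    idx = {e: i for i, e in enumerate(edges)}
    m = len(edges)
    full = (1 << m) - 1
    table = [0] * (1 << m)
    for C in enumerate_maximal_chain_subgraphs(G):
        cmask = 0
        for e in C.edges:
            cmask |= 1 << idx[e]
        table[full ^ cmask] += 1
    # subset-sum: after pass i, table[A] = sum over supersets differing in bit i
    for i in range(m):
        bit = 1 << i
        for mask in range(1 << m):
            if not mask & bit:
                table[mask] += table[mask | bit]
    return table


def count_covers(
    G: BipartiteGraph,
    k: int,
    *,
    max_edges: int = DEFAULT_EDGE_GUARD,
    force: bool = False,
) -> int:
    """c_k(G): the exact number of ordered k-tuples of maximal chain
    subgraphs whose union is E, by the alternating sum over all A of E."""
    if k < 1:
        raise ValueError("k must be >= 1")
    _guard(G.m, max_edges, force)
    if G.m == 0:
        return 0
    table = _avoiding_table(G)
    return sum(
        (-1 if mask.bit_count() & 1 else 1) * a**k
        for mask, a in enumerate(table)
    )


def minimum_cover_size(
    G: BipartiteGraph,
    *,
    max_edges: int = DEFAULT_EDGE_GUARD,
    force: bool = False,
) -> int:
    """Smallest k with c_k(G) != 0; 0 for an edgeless graph (convention).

    The a(.) table is computed once and reused across the k-scan.
    """
    if G.m == 0:
        return 0
    _guard(G.m, max_edges, force)
    table = _avoiding_table(G)
    signs = [-1 if mask.bit_count() & 1 else 1 for mask in range(len(table))]
    # a cover by maximal chain subgraphs of size <= |C(G)| always exists
    k_cap = table[0]
    for k in range(1, k_cap + 1):
        c_k = sum(s * a**k for s, a in zip(signs, table))
        if c_k != 0:
            return k
    raise RuntimeError("no cover found up to |C(G)|; this should be impossible")


def max_induced_matching(
    G: BipartiteGraph,
    *,
    max_edges: int = DEFAULT_EDGE_GUARD,
    force: bool = False,
) -> tuple[int, frozenset[Edge]]:
    """Largest set of edges pairwise inducing 2K2s, with one witness set.

    Two edges are independent here when their four endpoints are distinct
    and neither cross pair is an edge of ``G``; a maximum such set is a
    maximum clique of the pairwise-conflict graph on E (exact search).  Its
    size lower-bounds the minimum chain cover size.
    """
    _guard(G.m, max_edges, force)
    if G.m == 0:
        return 0, frozenset()
    edges = G.sorted_edges()
    H = nx.Graph()
    H.add_nodes_from(edges)
    for (e1, e2) in itertools.combinations(edges, 2):
        (u1, w1), (u2, w2) = e1, e2
        if u1 != u2 and w1 != w2 and (u1, w2) not in G.edges and (u2, w1) not in G.edges:
            H.add_edge(e1, e2)
    best: tuple[Edge, ...] = ()
    for clique in nx.find_cliques(H):
        if len(clique) > len(best):
            best = tuple(clique)
    return len(best), frozenset(best)


def max_induced_matching_size(G: BipartiteGraph, **kwargs) -> int:
    return max_induced_matching(G, **kwargs)[0]
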