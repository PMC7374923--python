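"""Polynomial-delay enumeration of all maximal chain subgraphs.

The enumerator rests on a decomposition of maximal chain subgraphs: if ``x``
is a node with largest neighbourhood in a maximal chain subgraph ``C`` of
``G``, then ``N_C(x) = N_G(x)`` is a maximal neighbourhood of ``G``, and
``C`` minus the edges at ``x`` is a maximal chain subgraph of the induced
subproblem ``G[U \\ {x}, N_G(x)]``.  Branching over one candidate per maximal
neighbourhood (twins deduplicated by smallest label) therefore visits every
maximal chain subgraph exactly once, depth-first, with polynomial work
between consecutive outputs.

A guarded exponential brute-force oracle over edge subsets is provided for
cross-checking on small instances; it shares no code with the enumerator.
"""

from __future__ import annotations

from typing import Callable, Iterator

from .graph import BipartiteGraph, ChainSubgraph, Edge, is_chain_subset

__all__ = [
    "compute_candidates",
    "enumerate_maximal_chain_subgraphs",
    "brute_force_maximal_chain_subgraphs",
    "node_count_bound",
    "edge_count_bound",
]


def compute_candidates(
    G: BipartiteGraph, U_sub: frozenset[str] | set[str], W_sub: frozenset[str] | set[str]
) -> set[str]:
    """One candidate node per maximal neighbourhood of ``G[U_sub, W_sub]``.

    A neighbourhood ``N(u)`` (restricted to ``W_sub``) is maximal when no
    other node's restricted neighbourhood strictly contains it.  Twins share
    a neighbourhood; the lexicographically smallest label represents them.
    Returns the empty set when the induced subgraph has no edges.
    """
    nbrs = {}
    for u in U_sub:
        nw = G.neighbours(u) & W_sub
        if nw:
            nbrs[u] = nw
    candidates: set[str] = set()
    seen: list[frozenset[str]] = []
    for u in sorted(nbrs):  # label order => smallest-label twin representative
        nu = frozenset(nbrs[u])
        if nu in seen:
            continue
        if any(nu < frozenset(other) for other in nbrs.values()):
            continue
        seen.append(nu)
        candidates.add(u)
    return candidates


def _enumerate_edge_sets(
    G: BipartiteGraph,
    prune: Callable[[frozenset[Edge]], bool] | None = None,
) -> Iterator[frozenset[Edge]]:
    """Depth-first recursion over candidates, yielding maximal chain edge sets.

    ``prune(committed)`` may declare a branch dead: no completion of the
    committed edge set will be emitted from it.  Used by the essential-edge
    enumerator; plain enumeration passes no prune.
    """
    if G.m == 0:
        return

    def rec(U_sub: frozenset[str], W_sub: frozenset[str], committed: frozenset[Edge]):
        if prune is not None and prune(committed):
            return
        candidates = compute_candidates(G, U_sub, W_sub)
        if not candidates:
            yield committed
            return
        for u in sorted(candidates):
            new_w = G.neighbours(u) & W_sub
            added = frozenset((u, w) for w in new_w)
            yield from rec(U_sub - {u}, frozenset(new_w), committed | added)

    yield from rec(frozenset(G.U), frozenset(G.W), frozenset())


def enumerate_maximal_chain_subgraphs(
    G: BipartiteGraph, pivot_side: str = "U"
) -> Iterator[ChainSubgraph]:
    """Stream all maximal chain subgraphs of ``G``, without repetition.

    Solutions are produced incrementally (polynomial delay); consuming the
    first does not require computing the rest.  ``pivot_side`` selects which
    side the recursion branches on: ``"U"`` (default), ``"W"``, or ``"auto"``
    for the smaller side — the emitted set of solutions is identical.

    An edgeless graph yields an empty stream.
    """
    if pivot_side not in ("U", "W", "auto"):
        raise ValueError("pivot_side must be 'U', 'W' or 'auto'")
    if pivot_side == "auto":
        pivot_side = "U" if len(G.U) <= len(G.W) else "W"
    if pivot_side == "W":
        for edge_set in _enumerate_edge_sets(G.transpose()):
            yield ChainSubgraph(G, frozenset((u, w) for (w, u) in edge_set))
        return
    for edge_set in _enumerate_edge_sets(G):
        yield ChainSubgraph(G, edge_set)


# ---------------------------------------------------------------------------
# Brute-force oracle

BRUTE_FORCE_EDGE_GUARD = 14


def brute_force_maximal_chain_subgraphs(
    G: BipartiteGraph, force: bool = False
) -> set[frozenset[Edge]]:
    """All inclusion-maximal 2K2-free edge subsets, by exhaustive search.

    Iterates over all 2^m edge subsets; refuses above m = 14 unless
    ``force=True``.  Intended as an independent test oracle only.
    """
    m = G.m
    if m > BRUTE_FORCE_EDGE_GUARD and not force:
        raise ValueError(
            f"brute force refused for m={m} > {BRUTE_FORCE_EDGE_GUARD} (use force=True)"
        )
    edges = G.sorted_edges()
    # bitmask neighbourhoods for a fast chainness test
    w_index = {w: j for j, w in enumerate(sorted(G.W))}
    chain_subsets: set[frozenset[Edge]] = set()
    for mask in range(1, 1 << m):
        subset = [edges[i] for i in range(m) if mask >> i & 1]
        nbr: dict[str, int] = {}
        for u, w in subset:
            nbr[u] = nbr.get(u, 0) | (1 << w_index[w])
        masks = sorted(nbr.values(), key=lambda b: b.bit_count())
        if all(a & b == a for a, b in zip(masks, masks[1:])):
            chain_subsets.add(frozenset(subset))
    maximal = {
        s
        for s in chain_subsets
        if not any(s | {e} in chain_subsets for e in G.edges - s)
    }
    return maximal


# ---------------------------------------------------------------------------
# Combinatorial upper bounds (tested invariants)


def node_count_bound(G: BipartiteGraph) -> int:
    """min(|U|, |W|)! — each maximal chain subgraph has a distinct
    neighbourhood ordering, so their number is bounded by the permutations
    of the smaller side."""
    import math

    return math.factorial(min(len(G.U), len(G.W)))


def edge_count_bound(G: BipartiteGraph) -> float:
    """2^(sqrt(m) * log2 m), the edge-sensitive bound on the number of
    maximal chain subgraphs."""
    import math

    m = G.m
    if m <= 1:
        return 1.0
    return 2.0 ** (math.sqrt(m) * math.log2(m))
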