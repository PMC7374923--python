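"""Enumeration of all minimal chain subgraph covers.

Not every maximal chain subgraph can occur in a minimal cover.  The ones
that can are characterised through *conflict sets*: for an edge ``e``,
``M_e`` is the set of edges forming an induced 2K2 with ``e`` in the host
graph.  An edge is *essential* when no other edge has a strictly larger
conflict set (the containment order on conflict sets mirrors, reversed, the
containment order on the families of maximal chains through each edge), and
a maximal chain subgraph belongs to some minimal cover exactly when it
contains an essential edge.

Minimal covers are then the minimal set covers of the hypergraph whose
ground set is the essential edges and whose hyperedges are the maximal
chain subgraphs containing at least one essential edge.  The minimal
set-cover enumerator here is an ordered include/exclude backtracking with
redundancy pruning; it emits every minimal cover exactly once (its
worst-case running time is not the point — correctness is).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .graph import BipartiteGraph, ChainSubgraph, Edge
from .enumerate_chains import _enumerate_edge_sets, enumerate_maximal_chain_subgraphs

__all__ = [
    "conflict_set",
    "ConflictIndex",
    "build_conflict_index",
    "essential_edges",
    "enumerate_essential_chain_subgraphs",
    "enumerate_minimal_set_covers",
    "ChainCover",
    "enumerate_minimal_covers",
]


def conflict_set(G: BipartiteGraph, e: Edge) -> frozenset[Edge]:
    """M_e: all edges forming an induced 2K2 with ``e`` in ``G``.

    These are the edges (u', w') with u' != u, w' != w and neither cross
    pair (u, w') nor (u', w) an edge of ``G``.
    """
    if e not in G.edges:
        raise ValueError(f"{e} is not an edge of G")
    u, w = e
    return frozenset(
        (u2, w2)
        for (u2, w2) in G.edges
        if u2 != u and w2 != w and (u, w2) not in G.edges and (u2, w) not in G.edges
    )


@dataclass(frozen=True)
class ConflictIndex:
    """Per-edge conflict sets and the derived essential-edge set."""

    conflicts: dict[Edge, frozenset[Edge]]
    essential: frozenset[Edge]


def build_conflict_index(G: BipartiteGraph) -> ConflictIndex:
    """Compute every M_e and the essential edges of ``G``.

    An edge is essential iff its conflict set is maximal under strict
    inclusion: edges with identical, inclusion-maximal conflict sets are all
    essential.  In a chain graph every M_e is empty, so every edge is
    essential.
    """
    conflicts = {e: conflict_set(G, e) for e in G.sorted_edges()}
    essential = frozenset(
        e
        for e, Me in conflicts.items()
        if not any(other > Me for other in conflicts.values())
    )
    return ConflictIndex(conflicts, essential)


def essential_edges(G: BipartiteGraph) -> frozenset[Edge]:
    return build_conflict_index(G).essential


def enumerate_essential_chain_subgraphs(G: BipartiteGraph) -> Iterator[ChainSubgraph]:
    """Stream the maximal chain subgraphs containing >= 1 essential edge.

    A maximal chain subgraph ``C`` contains an edge ``e`` iff ``C`` avoids
    all of ``M_e``; a recursion branch whose committed edges already meet
    every essential edge's conflict set can therefore never produce such a
    chain and is pruned.  A final membership filter guarantees correctness
    regardless of pruning strength.
    """
    index = build_conflict_index(G)
    ess = index.essential
    if not ess:
        return

    def prune(committed: frozenset[Edge]) -> bool:
        # dead iff committed intersects M_e for every essential e
        return all(committed & index.conflicts[e] for e in ess)

    for edge_set in _enumerate_edge_sets(G, prune=prune):
        if edge_set & ess:
            yield ChainSubgraph(G, edge_set)


# ---------------------------------------------------------------------------
# Minimal set covers


def enumerate_minimal_set_covers(
    ground: frozenset, family: Sequence[frozenset]
) -> Iterator[frozenset[int]]:
    """All minimal covers of ``ground`` by members of ``family``.

    Yields index sets (into ``family``); each emitted subfamily covers the
    ground set, removing any member breaks coverage, and every minimal cover
    appears exactly once.  Raises if some ground element is uncoverable.

    Ordered include/exclude backtracking: a member contributing nothing new
    over the already-included ones stays redundant in every superset, so the
    include branch is pruned; the exclude branch is pruned as soon as some
    ground element can no longer be covered by the remaining members.
    """
    ground = frozenset(ground)
    family = [frozenset(S) & ground for S in family]
    uncov = ground - frozenset().union(*family) if family else ground
    if uncov:
        raise ValueError(f"ground element(s) {sorted(uncov)} covered by no family member")
    n = len(family)
    # remaining[i] = union of family[i:]
    remaining = [frozenset()] * (n + 1)
    for i in range(n - 1, -1, -1):
        remaining[i] = remaining[i + 1] | family[i]

    def minimal(chosen: tuple[int, ...]) -> bool:
        for i in chosen:
            others = frozenset().union(*(family[j] for j in chosen if j != i)) \
                if len(chosen) > 1 else frozenset()
            if family[i] <= others:
                return False
        return True

    def rec(i: int, chosen: tuple[int, ...], covered: frozenset) -> Iterator[frozenset[int]]:
        if covered == ground:
            if minimal(chosen):
                yield frozenset(chosen)
            return
        if i == n or not (ground - covered) <= remaining[i]:
            return
        if not family[i] <= covered:  # include i (else it is redundant forever)
            yield from rec(i + 1, chosen + (i,), covered | family[i])
        yield from rec(i + 1, chosen, covered)  # exclude i

    yield from rec(0, (), frozenset())


@dataclass(frozen=True)
class ChainCover:
    """A set of maximal chain subgraphs whose union is the host edge set."""

    chains: tuple[ChainSubgraph, ...]
    minimal: bool = False

    @property
    def size(self) -> int:
        return len(self.chains)

    def edge_union(self) -> frozenset[Edge]:
        out: frozenset[Edge] = frozenset()
        for C in self.chains:
            out |= C.edges
        return out

    def chain_edge_sets(self) -> frozenset[frozenset[Edge]]:
        return frozenset(C.edges for C in self.chains)


def enumerate_minimal_covers(G: BipartiteGraph) -> Iterator[ChainCover]:
    """Stream all minimal chain subgraph covers of ``G``.

    Builds the set-cover instance on the essential edges, covered by the
    maximal chain subgraphs that contain at least one of them, enumerates
    its minimal set covers, and re-validates each result against the full
    edge set (the theory implies a minimal cover of the essential edges
    covers everything; the assertion would surface a violation rather than
    repair it silently).

    An edgeless graph yields the single empty cover.
    """
    if G.m == 0:
        yield ChainCover(chains=(), minimal=True)
        return
    chains = sorted(
        enumerate_essential_chain_subgraphs(G), key=lambda C: C.sorted_edges()
    )
    ess = essential_edges(G)
    family = [C.edges & ess for C in chains]
    for index_set in enumerate_minimal_set_covers(ess, family):
        cover = ChainCover(
            chains=tuple(chains[i] for i in sorted(index_set)), minimal=True
        )
        if cover.edge_union() != G.edges:
            raise RuntimeError(
                "minimal cover of the essential edges failed to cover E; "
                f"uncovered: {sorted(G.edges - cover.edge_union())}"
            )
        yield cover
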