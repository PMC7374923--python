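"""Interval-order view of chain subgraph problems.

A *bipartite poset* has its ground set split into two layers ``U`` and ``V``
with every related pair pointing from ``U`` to ``V`` (so transitivity and
antisymmetry are automatic).  Such a poset is an interval order exactly when
its comparability graph is a chain graph, and its *interval dimension* —
the minimum number of interval order extensions intersecting to it — equals
the minimum chain cover size of the bipartite complement of the
comparability graph.  Maximal chain subgraphs of the comparability graph are
maximal interval order reductions; maximal chain subgraphs of the
complement, read back as complements, are minimal interval order extensions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterator

from .graph import BipartiteGraph, FormatError, bipartite_complement, is_chain_graph
from .enumerate_chains import enumerate_maximal_chain_subgraphs
from .cover_count import DEFAULT_EDGE_GUARD, minimum_cover_size

__all__ = [
    "BipartitePoset",
    "read_relation_list",
    "comparability_graph",
    "poset_from_comparability",
    "interval_dimension",
    "enumerate_interval_posets",
]


@dataclass(frozen=True)
class BipartitePoset:
    """Two-layer poset: ``relation`` is a set of (u, v) pairs, u in U, v in V.

    Reflexive pairs are implicit and not stored.
    """

    U: frozenset[str]
    V: frozenset[str]
    relation: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.U & self.V:
            raise ValueError("layers U and V must be disjoint")
        for u, v in self.relation:
            if u not in self.U or v not in self.V:
                raise ValueError(f"related pair ({u!r}, {v!r}) leaves U x V")


def read_relation_list(source) -> BipartitePoset:
    """Parse a relation TSV (u TAB v per pair; ``#U:``/``#V:`` ground sets)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    U: set[str] = set()
    V: set[str] = set()
    rel: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#U:"):
            U.update(line[3:].split())
            continue
        if line.startswith("#V:"):
            V.update(line[3:].split())
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'u<TAB>v', got {line!r}")
        u, v = parts[0].strip(), parts[1].strip()
        U.add(u)
        V.add(v)
        rel.add((u, v))
    return BipartitePoset(frozenset(U), frozenset(V), frozenset(rel))


def comparability_graph(H: BipartitePoset) -> BipartiteGraph:
    """Edge (u, v) iff u <= v in ``H``."""
    return BipartiteGraph(H.U, H.V, H.relation)


def poset_from_comparability(G: BipartiteGraph) -> BipartitePoset:
    """Inverse of :func:`comparability_graph`."""
    return BipartitePoset(G.U, G.W, G.edges)


def interval_dimension(
    H: BipartitePoset, *, max_edges: int = DEFAULT_EDGE_GUARD, force: bool = False
) -> int:
    """Idim(H): minimum chain cover size of the bipartite complement of G(H).

    When that complement is edgeless (complete comparability graph, already
    an interval order) the dimension is 1 by convention — a realisable order
    needs at least one extension.
    """
    B = bipartite_complement(comparability_graph(H))
    if B.m == 0:
        return 1
    return minimum_cover_size(B, max_edges=max_edges, force=force)


def enumerate_interval_posets(
    H: BipartitePoset, mode: str
) -> Iterator[BipartitePoset]:
    """Stream minimal interval order extensions or maximal reductions of ``H``.

    ``mode="reductions"``: each maximal chain subgraph of the comparability
    graph G(H), read back as a poset (a maximal sub-relation that is an
    interval order).  ``mode="extensions"``: for each maximal chain subgraph
    C of the bipartite complement of G(H), the poset whose relation is
    (U x V) minus C's edges — a minimal interval-order super-relation.
    Streams inherit the chain enumerator's determinism and freedom from
    duplicates.
    """
    G = comparability_graph(H)
    if mode == "reductions":
        if G.m == 0:
            yield H  # the empty relation is its own (interval) reduction
            return
        for C in enumerate_maximal_chain_subgraphs(G):
            yield BipartitePoset(H.U, H.V, frozenset(C.edges))
        return
    if mode == "extensions":
        B = bipartite_complement(G)
        if B.m == 0:
            yield H  # already an interval order with full comparability
            return
        full = frozenset((u, v) for u in H.U for v in H.V)
        for C in enumerate_maximal_chain_subgraphs(B):
            yield BipartitePoset(H.U, H.V, full - C.edges)
        return
    raise ValueError("mode must be 'reductions' or 'extensions'")
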