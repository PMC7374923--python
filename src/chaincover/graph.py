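"""Bipartite incompatibility graphs and chain-graph recognition.

Cytoplasmic incompatibility data arrive as a 0/1 matrix ``C`` with males in
rows and females in columns; ``C[i, j] = 1`` records an incompatible cross.
The matrix is equivalently the adjacency matrix of a bipartite graph with the
males on one side (``U``), the females on the other (``W``) and one edge per
incompatible cross.  A *chain graph* is a bipartite graph with no induced
2K2 — equivalently one whose neighbourhoods on either side are totally
ordered by inclusion — and is exactly the incompatibility pattern a single
Lock/Key molecule pair can produce.

Edges are canonically stored and emitted as ``(male, female)`` pairs sorted
lexicographically, so downstream enumeration output is reproducible
byte-for-byte.  Isolated nodes are first-class: membership in ``U``/``W``
does not require incidence, and edge-centric algorithms simply ignore them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "IncompatibilityMatrix",
    "BipartiteGraph",
    "ChainSubgraph",
    "NotAChainGraphError",
    "read_incompatibility_matrix",
    "read_edge_list",
    "write_edge_list",
    "graph_from_matrix",
    "matrix_from_graph",
    "is_chain_graph",
    "find_induced_2k2",
    "neighbourhood_ordering",
    "bipartite_complement",
]

Edge = tuple[str, str]


class FormatError(ValueError):
    """Raised when an input file violates the documented matrix/edge formats."""


class NotAChainGraphError(ValueError):
    """Raised when a chain subgraph is required but the edge set contains a 2K2.

    Carries the offending pair of edges as ``witness``.
    """

    def __init__(self, witness: tuple[Edge, Edge]):
        self.witness = witness
        super().__init__(f"edge set contains an induced 2K2: {witness[0]} / {witness[1]}")


@dataclass(frozen=True)
class IncompatibilityMatrix:
    """A labelled 0/1 incompatibility matrix (rows = males, columns = females)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate male label {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate female label {dup!r}")
        arr = df.to_numpy()
        bad = (arr != 0) & (arr != 1)
        if bad.any():
            i, j = next(zip(*bad.nonzero()))
            raise FormatError(
                f"entry at row {df.index[i]!r}, column {df.columns[j]!r} "
                f"is {df.iat[i, j]!r}; expected 0 or 1"
            )

    @property
    def row_labels(self) -> list[str]:
        return [str(x) for x in self.data.index]

    @property
    def col_labels(self) -> list[str]:
        return [str(x) for x in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __getitem__(self, key: tuple[str, str]) -> int:
        male, female = key
        return int(self.data.at[male, female])

    def to_csv(self) -> str:
        return self.data.to_csv()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncompatibilityMatrix):
            return NotImplemented
        return self.data.equals(other.data)


class BipartiteGraph:
    """A node-labelled bipartite graph; edges mean incompatible crosses.

    ``U`` holds male labels, ``W`` female labels.  The same label may not
    occur on both sides.  Construction is O(m); neighbourhoods are indexed.
    """

    __slots__ = ("U", "W", "edges", "_nbr_u", "_nbr_w")

    def __init__(self, U: Iterable[str], W: Iterable[str], edges: Iterable[Edge]):
        self.U = frozenset(U)
        self.W = frozenset(W)
        overlap = self.U & self.W
        if overlap:
            raise ValueError(f"label(s) {sorted(overlap)} appear on both sides")
        es = set()
        nbr_u: dict[str, set[str]] = {u: set() for u in self.U}
        nbr_w: dict[str, set[str]] = {w: set() for w in self.W}
        for u, w in edges:
            if u not in self.U or w not in self.W:
                raise ValueError(f"edge ({u!r}, {w!r}) has an endpoint outside U x W")
            es.add((u, w))
            nbr_u[u].add(w)
            nbr_w[w].add(u)
        self.edges: frozenset[Edge] = frozenset(es)
        self._nbr_u = {u: frozenset(s) for u, s in nbr_u.items()}
        self._nbr_w = {w: frozenset(s) for w, s in nbr_w.items()}

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.U) + len(self.W)

    @property
    def m(self) -> int:
        return len(self.edges)

    def neighbours(self, v: str) -> frozenset[str]:
        if v in self._nbr_u:
            return self._nbr_u[v]
        if v in self._nbr_w:
            return self._nbr_w[v]
        raise KeyError(v)

    def incident_edges(self, v: str) -> frozenset[Edge]:
        if v in self._nbr_u:
            return frozenset((v, w) for w in self._nbr_u[v])
        if v in self._nbr_w:
            return frozenset((u, v) for u in self._nbr_w[v])
        raise KeyError(v)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def subgraph(self, U_sub: Iterable[str], W_sub: Iterable[str]) -> "BipartiteGraph":
        """Node-induced subgraph on ``U_sub`` | ``W_sub``."""
        Us, Ws = frozenset(U_sub), frozenset(W_sub)
        if not Us <= self.U or not Ws <= self.W:
            raise ValueError("subgraph sides must be subsets of U and W")
        es = [(u, w) for (u, w) in self.edges if u in Us and w in Ws]
        return BipartiteGraph(Us, Ws, es)

    def transpose(self) -> "BipartiteGraph":
        """Swap the two sides (edges become (female, male))."""
        return BipartiteGraph(self.W, self.U, [(w, u) for (u, w) in self.edges])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteGraph):
            return NotImplemented
        return self.U == other.U and self.W == other.W and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.U, self.W, self.edges))

    def __repr__(self) -> str:
        return f"BipartiteGraph(|U|={len(self.U)}, |W|={len(self.W)}, m={self.m})"


@dataclass(frozen=True)
class ChainSubgraph:
    """An edge subset of a host graph inducing no 2K2.

    Following the edge-induced convention, a chain subgraph is identified with
    its edges; its node set is implied (endpoints of the edges).  Validation
    is performed at construction and raises :class:`NotAChainGraphError` with
    a witness pair on failure.
    """

    host: BipartiteGraph
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        if not self.edges <= self.host.edges:
            raise ValueError("chain subgraph edges must belong to the host graph")
        witness = _find_2k2_in_edge_set(self.edges)
        if witness is not None:
            raise NotAChainGraphError(witness)

    @property
    def nodes_u(self) -> frozenset[str]:
        return frozenset(u for u, _ in self.edges)

    @property
    def nodes_w(self) -> frozenset[str]:
        return frozenset(w for _, w in self.edges)

    def neighbours_u(self, u: str) -> frozenset[str]:
        return frozenset(w for uu, w in self.edges if uu == u)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChainSubgraph):
            return NotImplemented
        return self.host == other.host and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)


# ---------------------------------------------------------------------------
# I/O


def read_incompatibility_matrix(source, *, header: bool = True) -> IncompatibilityMatrix:
    """Parse a CSV incompatibility matrix.

    With ``header=True`` (default) the first row carries the female labels
    (first cell empty or arbitrary) and the first column the male labels.
    With ``header=False`` the file is a bare 0/1 body and labels are
    auto-generated ``M1..`` / ``F1..``.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    try:
        if header:
            text = source.read()
            # pandas mangles duplicate column names; validate the raw header
            head_cells = text.splitlines()[0].split(",")[1:] if text else []
            if len(head_cells) != len(set(head_cells)):
                dup = next(c for c in head_cells if head_cells.count(c) > 1)
                raise FormatError(f"duplicate female label {dup!r}")
            df = pd.read_csv(io.StringIO(text), index_col=0, dtype=str)
        else:
            df = pd.read_csv(source, header=None, dtype=str)
            df.index = [f"M{i + 1}" for i in range(len(df.index))]
            df.columns = [f"F{j + 1}" for j in range(len(df.columns))]
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"malformed CSV: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer entry in matrix body: {exc}") from exc
    if df.isna().any().any():
        raise FormatError("missing entries in matrix body (ragged rows?)")
    return IncompatibilityMatrix(df)


def read_edge_list(source) -> BipartiteGraph:
    """Parse a two-column TSV edge list (male TAB female, one edge per line).

    Isolated nodes may be declared with ``#U: a b c`` / ``#W: x y`` comment
    headers; other ``#`` lines are ignored.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    U: set[str] = set()
    W: set[str] = set()
    edges: list[Edge] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#U:"):
            U.update(line[3:].split())
            continue
        if line.startswith("#W:"):
            W.update(line[3:].split())
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 'male<TAB>female', got {line!r}")
        u, w = parts[0].strip(), parts[1].strip()
        U.add(u)
        W.add(w)
        edges.append((u, w))
    return BipartiteGraph(U, W, edges)


def write_edge_list(G: BipartiteGraph) -> str:
    lines = [
        "#U: " + " ".join(sorted(G.U)),
        "#W: " + " ".join(sorted(G.W)),
    ]
    lines += [f"{u}\t{w}" for u, w in G.sorted_edges()]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Matrix <-> graph


def graph_from_matrix(C: IncompatibilityMatrix) -> BipartiteGraph:
    """The bipartite graph whose adjacency matrix is ``C`` (1 = edge)."""
    df = C.data
    edges = [
        (str(male), str(female))
        for male in df.index
        for female in df.columns
        if df.at[male, female] == 1
    ]
    return BipartiteGraph(C.row_labels, C.col_labels, edges)


def matrix_from_graph(
    G: BipartiteGraph,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> IncompatibilityMatrix:
    """Adjacency matrix of ``G`` with rows/columns in the given orders.

    Orders default to sorted labels and must cover each side exactly once.
    """
    rows = list(row_order) if row_order is not None else sorted(G.U)
    cols = list(col_order) if col_order is not None else sorted(G.W)
    if sorted(rows) != sorted(G.U) or len(rows) != len(G.U):
        raise ValueError("row_order must be a permutation of U")
    if sorted(cols) != sorted(G.W) or len(cols) != len(G.W):
        raise ValueError("col_order must be a permutation of W")
    df = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for u, w in G.edges:
        df.at[u, w] = 1
    return IncompatibilityMatrix(df)


# ---------------------------------------------------------------------------
# Chain-graph recognition


def _find_2k2_in_edge_set(edges: Iterable[Edge]) -> tuple[Edge, Edge] | None:
    """Exhaustive induced-2K2 search within an edge set (O(pairs))."""
    es = set(edges)
    elist = sorted(es)
    for i, (u, w) in enumerate(elist):
        for (u2, w2) in elist[i + 1:]:
            if u != u2 and w != w2 and (u, w2) not in es and (u2, w) not in es:
                return ((u, w), (u2, w2))
    return None


def find_induced_2k2(G: BipartiteGraph) -> tuple[Edge, Edge] | None:
    """Return a pair of edges inducing a 2K2 in ``G``, or None."""
    return _find_2k2_in_edge_set(G.edges)


def is_chain_subset(edges: Iterable[Edge]) -> bool:
    """True iff the edge set, taken alone, induces no 2K2.

    Checked via nested neighbourhoods (sort by degree, verify the inclusion
    chain), which is the defining equivalence for chain graphs.
    """
    nbr: dict[str, set[str]] = {}
    for u, w in edges:
        nbr.setdefault(u, set()).add(w)
    sets = sorted(nbr.values(), key=len)
    return all(a <= b for a, b in zip(sets, sets[1:]))


def is_chain_graph(G: BipartiteGraph) -> bool:
    """True iff ``G`` contains no induced 2K2.

    Uses the nested-neighbourhood characterisation; the quadratic witness
    search is available as :func:`find_induced_2k2` and the two must agree.
    """
    return is_chain_subset(G.edges)


def neighbourhood_ordering(C: ChainSubgraph) -> tuple[list[str], list[str]]:
    """Orderings of the host's U and W sides with nested within-chain
    neighbourhoods.

    Nodes outside the chain (empty neighbourhood) come first; ties (twins)
    are broken by label order.  The W-side ordering is the analogous one and
    yields the staircase row/column permutation.
    """
    nbr_u: dict[str, frozenset[str]] = {u: frozenset() for u in C.host.U}
    nbr_w: dict[str, frozenset[str]] = {w: frozenset() for w in C.host.W}
    for u, w in C.edges:
        nbr_u[u] = nbr_u[u] | {w}
        nbr_w[w] = nbr_w[w] | {u}
    u_order = sorted(C.host.U, key=lambda u: (len(nbr_u[u]), u))
    w_order = sorted(C.host.W, key=lambda w: (len(nbr_w[w]), w))
    return u_order, w_order


def bipartite_complement(G: BipartiteGraph) -> BipartiteGraph:
    """The graph on the same sides whose edges are the non-edges of ``G``."""
    edges = [(u, w) for u in G.U for w in G.W if (u, w) not in G.edges]
    return BipartiteGraph(G.U, G.W, edges)
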