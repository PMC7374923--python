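"""The quantitative Lock/Key model layer.

Each Wolbachia-like strain deposits a Lock (toxin) quantity in sperm and a
Key (antitoxin) quantity in eggs.  With ``k`` molecule pairs, the model is a
pair of nonnegative-integer matrices: ``L`` (males x k) and ``K``
(females x k).  The pair *explains* an incompatibility matrix ``C`` when

    C[i, j] = 0  <=>  K[j, l] >= L[i, l] for every molecule pair l,

i.e. a cross succeeds exactly when the female carries enough Key for every
Lock of the male.  A single molecule pair can produce exactly the chain
graphs, and a cover of the incompatibility graph by k chain subgraphs
translates column-by-column into an explaining (L, K) pair — so the minimum
number of molecule pairs equals the minimum chain cover size.

Only the relative order of the quantities within a column matters; any
strictly increasing relabelling of a column's values (applied jointly to L
and K) preserves the explains relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .graph import (
    BipartiteGraph,
    ChainSubgraph,
    IncompatibilityMatrix,
    matrix_from_graph,
)

__all__ = [
    "LockKeyPair",
    "explains",
    "degree_classes",
    "lockkey_from_chain",
    "lockkey_from_cover",
    "matrix_from_lockkey",
]


@dataclass(frozen=True)
class LockKeyPair:
    """Lock quantities ``L`` (males x k) and Key quantities ``K`` (females x k).

    Columns are named ``lock_1..lock_k`` / ``key_1..key_k``; entries are
    nonnegative integers, 0 meaning absence of the molecule.
    """

    L: pd.DataFrame
    K: pd.DataFrame

    def __post_init__(self) -> None:
        if self.L.shape[1] != self.K.shape[1]:
            raise ValueError("L and K must have the same number of columns")
        for df, name in ((self.L, "L"), (self.K, "K")):
            arr = df.to_numpy()
            if arr.size and ((arr < 0).any() or (arr != arr.astype(int)).any()):
                raise ValueError(f"{name} entries must be nonnegative integers")

    @property
    def k(self) -> int:
        return self.L.shape[1]

    @property
    def males(self) -> list[str]:
        return [str(x) for x in self.L.index]

    @property
    def females(self) -> list[str]:
        return [str(x) for x in self.K.index]


def explains(
    C: IncompatibilityMatrix, lk: LockKeyPair
) -> tuple[bool, tuple[str, str] | None]:
    """Does (L, K) explain ``C``?  Returns (verdict, first counterexample).

    The counterexample, when present, is the first (male, female) pair — in
    label order — whose observed compatibility contradicts the model.
    """
    if sorted(lk.males) != sorted(C.row_labels) or sorted(lk.females) != sorted(
        C.col_labels
    ):
        raise ValueError("Lock/Key labels do not match the matrix labels")
    for male in sorted(C.row_labels):
        for female in sorted(C.col_labels):
            opens_all = all(
                lk.K.at[female, f"key_{l}"] >= lk.L.at[male, f"lock_{l}"]
                for l in range(1, lk.k + 1)
            )
            if (C[male, female] == 0) != opens_all:
                return False, (male, female)
    return True, None


def degree_classes(C: ChainSubgraph) -> dict[int, frozenset[str]]:
    """Group the chain's U-side nodes by within-chain degree.

    Class ``r`` holds the males with exactly ``r`` within-chain neighbours
    (twins share a class); class indices can skip values when classes are
    empty.  Males absent from the chain form class 0.
    """
    classes: dict[int, set[str]] = {}
    for u in C.host.U:
        r = len(C.neighbours_u(u))
        classes.setdefault(r, set()).add(u)
    return {r: frozenset(s) for r, s in classes.items()}


def lockkey_from_chain(C: ChainSubgraph) -> LockKeyPair:
    """One Lock/Key column for a single chain subgraph.

    A male in degree class ``r`` receives Lock quantity ``r`` (0 when absent
    from the chain).  A female receives Key quantity ``r - 1`` where ``r``
    is the smallest class index whose neighbourhood contains her; a female
    in no class neighbourhood receives the largest class index ``d`` —
    enough Keys for every Lock in this column.  The resulting pair explains
    the matrix of the chain alone.
    """
    classes = degree_classes(C)
    d = max(classes)  # largest within-chain degree (0 for an edgeless chain)
    L = pd.Series(0, index=sorted(C.host.U), dtype=int)
    for r, members in classes.items():
        for u in members:
            L[u] = r
    # nested neighbourhoods: N(B_1) <= N(B_2) <= ... for nonempty classes
    nonempty = sorted(r for r in classes if r > 0)
    class_nbhd = {r: C.neighbours_u(min(classes[r])) for r in nonempty}
    K = pd.Series(d, index=sorted(C.host.W), dtype=int)
    for w in C.host.W:
        for r in nonempty:
            if w in class_nbhd[r]:
                K[w] = r - 1
                break
    return LockKeyPair(L.to_frame("lock_1"), K.to_frame("key_1"))


def lockkey_from_cover(
    C: IncompatibilityMatrix, cover: Iterable[ChainSubgraph]
) -> LockKeyPair:
    """Lock/Key matrices with one column per chain of a cover of B(C).

    Requires the chains to cover every incompatible cross; the constructed
    pair is asserted to explain ``C`` before being returned.
    """
    from .graph import graph_from_matrix

    G = graph_from_matrix(C)
    chains = list(cover)
    covered: frozenset = frozenset()
    for ch in chains:
        if ch.host != G and not ch.edges <= G.edges:
            raise ValueError("cover chain has edges outside B(C)")
        covered |= ch.edges
    if covered != G.edges:
        raise ValueError(
            f"cover misses edges: {sorted(G.edges - covered)}"
        )
    males, females = sorted(G.U), sorted(G.W)
    L = pd.DataFrame(index=males, dtype=int)
    K = pd.DataFrame(index=females, dtype=int)
    for col, ch in enumerate(chains, start=1):
        single = lockkey_from_chain(ChainSubgraph(G, ch.edges))
        L[f"lock_{col}"] = single.L["lock_1"]
        K[f"key_{col}"] = single.K["key_1"]
    pair = LockKeyPair(L.astype(int), K.astype(int))
    ok, witness = explains(C, pair)
    if not ok:
        raise AssertionError(f"constructed Lock/Key pair fails to explain C at {witness}")
    return pair


def matrix_from_lockkey(lk: LockKeyPair) -> IncompatibilityMatrix:
    """The incompatibility matrix a Lock/Key pair predicts.

    ``C[i, j] = 0`` iff the female opens every Lock (vacuously true when
    k = 0, yielding the all-zero matrix).
    """
    males, females = sorted(lk.males), sorted(lk.females)
    df = pd.DataFrame(0, index=males, columns=females, dtype=int)
    for male in males:
        for female in females:
            opens_all = all(
                lk.K.at[female, f"key_{l}"] >= lk.L.at[male, f"lock_{l}"]
                for l in range(1, lk.k + 1)
            )
            if not opens_all:
                df.at[male, female] = 1
    return IncompatibilityMatrix(df)
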