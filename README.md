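# chaincover

Chain subgraph covers of bipartite incompatibility graphs, for the
quantitative Lock/Key model of cytoplasmic incompatibility (CI).

## The problem

*Wolbachia* and related intracellular bacteria manipulate arthropod
reproduction: a cross between an infected male and a female lacking the
matching infection fails.  Crossing experiments between `n1` male and `n2`
female lines are recorded as a 0/1 matrix `C` (males in rows; `C[i,j] = 1`
means the cross is incompatible).  Under the quantitative Lock/Key model,
each molecule pair `l` deposits a Lock quantity `L[i,l]` in the sperm of
male `i` and a Key quantity `K[j,l]` in the eggs of female `j`, and

    C[i,j] = 0  ⇔  K[j,l] ≥ L[i,l]  for every l = 1..k,

i.e. a cross succeeds exactly when the female has enough Key for every Lock.
Reading `C` as the adjacency matrix of a bipartite graph `B(C)` (edges =
incompatible crosses), a single molecule pair generates precisely the
**chain graphs** — bipartite graphs with no induced 2K2, equivalently with
neighbourhoods totally ordered by inclusion — and `C` is explainable with
`k` pairs iff `B(C)` has an edge cover by `k` chain subgraphs.  The minimum
number of molecule pairs is therefore the minimum chain subgraph cover size
(NP-hard in general), and because biologically different optimal solutions
coexist, *enumerating* all minimal covers matters as much as finding one.

## What the package computes

* **All maximal chain subgraphs** of a bipartite graph, streamed without
  repetition with polynomial delay (branching on one candidate node per
  maximal neighbourhood), plus a guarded brute-force oracle and the
  combinatorial bounds `|𝒞(G)| ≤ min(|U|,|W|)!` and
  `|𝒞(G)| ≤ 2^(√m·log₂ m)` as testable properties.
* **Exact minimum cover size** via inclusion–exclusion: the number of
  covers of size `k` is `c_k(G) = Σ_{A⊆E} (−1)^|A| a(A)^k`, with `a(A)` the
  number of maximal chain subgraphs avoiding `A`; the answer is the smallest
  `k` with `c_k ≠ 0` (exact integer arithmetic, 2^m-term sum behind an edge
  guard).
* **All minimal chain covers**, through conflict sets `M_e` (edges forming
  a 2K2 with `e`), essential edges (maximal `M_e`), and minimal set covers
  of the induced hypergraph.
* **Lock/Key matrices** from any cover (one column per chain, quantities
  from the nested degree classes), the `explains` predicate with
  counterexamples, and the generative inverse.
* **Interval orders**: the interval dimension of a bipartite poset equals
  the minimum chain cover size of the bipartite complement of its
  comparability graph; minimal interval extensions and maximal reductions
  are enumerated via the chain enumerator.
* **Synthetic generators**: the extremal antimatching family `A_n`
  (complete bipartite minus a perfect matching, exactly `(n/2)!` maximal
  chain subgraphs), seeded random bipartite graphs, planted covers, and the
  worked two-male/three-female example.

## Worked example

```python
>>> import chaincover as cc
>>> matrix, G, _ = cc.fig2_fixture()       # M1 incompatible with F1,F2,F3; M2 with F1
>>> [c.sorted_edges() for c in cc.enumerate_maximal_chain_subgraphs(G)]
[[('M1', 'F1'), ('M1', 'F2'), ('M1', 'F3'), ('M2', 'F1')]]
>>> cc.minimum_cover_size(G)
1
>>> lk = cc.lockkey_from_cover(matrix, cc.enumerate_maximal_chain_subgraphs(G))
>>> lk.L["lock_1"].to_dict(), lk.K["key_1"].to_dict()
({'M1': 3, 'M2': 1}, {'F1': 0, 'F2': 2, 'F3': 2})
>>> cc.explains(matrix, lk)
(True, None)
```

One chain covers the whole graph, so one Lock/Key molecule pair suffices:
male M1 carries Lock quantity 3 (incompatible with every female, since no
Key reaches 3), male M2 carries 1, and female F1's Key quantity 0 leaves
her incompatible with both males while F2/F3 (Key 2) resist only M1.

The same pipeline from the shell:

```sh
chaincover generate fig2 --as-matrix > fig2.csv
chaincover enumerate-chains fig2.csv     # NDJSON, one chain per line
chaincover min-cover fig2.csv            # -> minimum cover size: 1
chaincover lockkey fig2.csv              # locks.csv / keys.csv tables
```

A published *Culex pipiens* crossing matrix (16 maximal chain subgraphs,
minimum cover 4) is a known benchmark; it is not redistributed here but any
such CSV can be fed to the same commands.

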