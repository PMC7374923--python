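# Methods

## Model

Crossing data are a 0/1 matrix `C` (rows = male lines, columns = female
lines, 1 = incompatible cross), equivalently a bipartite graph
`G = (U ∪ W, E)` with one edge per incompatible cross.  The quantitative
Lock/Key model posits `k` toxin/antitoxin molecule pairs with nonnegative
integer quantities `L` (males × k) and `K` (females × k); a cross `(i, j)`
succeeds iff `K[j,l] ≥ L[i,l]` for all `l`.  The patterns a single pair can
produce are exactly the chain graphs (no induced 2K2; neighbourhoods nested
by inclusion), so explaining `C` with `k` pairs is the same as covering the
edges of `B(C)` with `k` chain subgraphs.  All algorithms work on
*edge-induced* chain subgraphs: a chain subgraph is identified with its edge
set, its nodes implied.  The model assumes the data are complete and
noise-free; inference from partially observed or noisy matrices is out of
scope.

## Algorithms and numerical choices

**Maximal chain enumeration.** Any maximal chain subgraph's largest
neighbourhood is a maximal neighbourhood of the host graph, and removing
that node and restricting the female side to its neighbourhood leaves a
maximal chain subgraph of the reduced instance.  The enumerator branches
depth-first over one *candidate* per maximal neighbourhood — twins (equal
neighbourhoods) are represented by the lexicographically smallest label, and
candidates are visited in label order, making the emission order fully
deterministic.  Each recursion level shrinks `U` by one node, giving
polynomial delay (`O(n²m)` between solutions) and no repetitions.  The
recursion branches on the `U` side by default; `pivot_side="W"`/`"auto"`
transposes first (useful when `|W| < |U|`) and yields the identical solution
set.  Edgeless graphs yield an empty stream.  Chains are emitted as
lexicographically sorted `(male, female)` edge lists so output is
reproducible byte-for-byte.

**Cover counting.** `c_k(G) = Σ_{A⊆E} (−1)^{|A|} a(A)^k` counts *ordered*
k-tuples with repetition of maximal chain subgraphs whose union is `E`
(`a(A)^k` factorises over independent choices; the ordered/unordered
distinction does not affect the minimum-`k` extraction, and the tuple
semantics is pinned by an explicit tuple-counting oracle test).  The
single-subset routine `count_avoiding` enumerates the maximal chain
subgraphs of `(U ∪ W, E \ A)` and keeps those still maximal in `G`.  The
full sum instead builds the entire `a(·)` table at once: each maximal chain
subgraph is an edge bitmask, `C ∩ A = ∅ ⇔ A ⊆ complement(C)`, and a
subset-sum (zeta) transform over the 2^m masks produces every `a(A)` in
`O(2^m · m)` — the table is then reused across the whole `k`-scan in
`minimum_cover_size`.  A property test asserts the table agrees with
`count_avoiding` on random subsets.  All arithmetic is exact Python
integers (`a(∅)^k` overflows fixed width quickly).  The 2^m-term sum is
guarded at `m ≤ 20` by default (`--max-edges`/`force` to override): memory
for the table, not time, is the binding constraint.  Minimum cover size of
an edgeless graph is 0 by convention, and the smallest `k` with
`c_k ≠ 0` never exceeds `|𝒞(G)| = a(∅)` (some subset of the maximal chains
always covers `E`).

**Induced matchings.** A set of edges pairwise forming induced 2K2s
lower-bounds the cover size (no chain subgraph can contain two of them).
The maximum such set is found as a maximum clique of the pairwise-conflict
graph on `E`, using networkx's exact maximal-clique search behind the same
edge guard; a witness set is returned.

**Essential edges and minimal covers.** `M_e` is the set of edges forming
an induced 2K2 with `e` (computed by the direct four-endpoint test; the
relation is symmetric).  The containment order on the families
`𝒞_e = {maximal chains through e}` is the reverse of containment on
conflict sets (`𝒞_e ⊆ 𝒞_{e'} ⇔ M_e ⊇ M_{e'}`), so essential edges — those
whose `𝒞_e` is not a strict superset of another — are exactly the edges
with inclusion-maximal `M_e`.  Edges sharing an inclusion-maximal conflict
set are all essential (their `𝒞` families coincide).  A maximal chain
subgraph belongs to some minimal cover iff it contains an essential edge,
and it contains `e` iff it avoids all of `M_e`; the essential-chain
enumerator prunes recursion branches whose committed edges already meet
every essential edge's conflict set, with a final membership filter so
correctness never depends on pruning strength (the polynomial-delay bound
of the pruned enumeration is not claimed).  Minimal covers are then the
minimal set covers of the hypergraph (ground = essential edges, hyperedges
= essential chains restricted to them), enumerated by ordered
include/exclude backtracking: a member adding nothing over the already
included ones stays redundant in every superset (include branch pruned), a
ground element no remaining member can cover kills the exclude branch, and
a final irredundancy check accepts exactly the minimal covers, each once.
Correctness, not the quasi-polynomial worst-case bound, is the contract.
Each emitted cover is re-validated against the full edge set; the theory
implies this always holds, and a violation would be raised as a finding,
not silently repaired.  The edgeless graph yields the single empty cover.

**Lock/Key construction.** For one chain, group the males by within-chain
degree into classes `B_r` (`r` = degree; indices skip empty classes — no
re-compaction, so the worked example's quantities 3 and 1 are reproduced
as printed); male in `B_r` gets Lock `r`, absent males get 0.  A female
covered by some class neighbourhood gets Key `r − 1` for the smallest such
class `r`; a female outside every class neighbourhood gets the largest
class index `d` ("enough Keys for every Lock in this column"), the
minimal-information completion that makes the explains relation hold
globally.  A cover produces one column per chain, and the constructed pair
is asserted to explain the input matrix before being returned.  Only the
relative order of quantities within a column is meaningful; any jointly
applied strictly increasing relabelling preserves explains (tested).

**Interval orders.** For a two-layer poset `H` (relation ⊆ U × V, so
transitivity is automatic), the interval dimension equals the minimum chain
cover size of the bipartite complement of the comparability graph.  When
that complement is edgeless the dimension is reported as 1 — a realisable
order needs at least one extension; the degenerate case has no standard
value and the convention is ours.  Maximal reductions are the maximal chain
subgraphs of the comparability graph read back as posets; minimal
extensions are the set-complements of the maximal chain subgraphs of the
bipartite complement.

## Synthetic data

`antimatching(n)` is the extremal family (complete bipartite minus a
perfect matching): exactly `(n/2)!` maximal chain subgraphs, one per
permutation of `U`, minimum cover 2 and maximum induced matching 2 for
`n ≥ 6` — fixed laws used as exact oracles.  `random_bipartite(n1, n2, p,
seed)` draws each potential edge independently; `planted_cover` unions `k`
random chain graphs (random male permutation, sorted neighbourhood sizes,
nested prefixes of a random female permutation), guaranteeing cover size
≤ k.  All generators are pure functions of their parameters and seed.
These graphs emulate the combinatorial structure of incompatibility data
— not its biology: real matrices are small, sparse-ish and highly
structured, and real data carry measurement noise and missing crosses,
which nothing here models.  Passing tests therefore certify algorithmic
correctness on the combinatorial object, not robustness to noisy assays.

## Test problem sizes

The exhaustive oracles (all 2^m edge subsets; all subsets of the maximal
chains; all ordered k-tuples) are run on a seeded corpus of 200 random
bipartite graphs with 2–5 nodes per side and 1–12 edges — sizes at which
every oracle is exact and the whole suite runs in seconds.  The brute-force
chain oracle refuses `m > 14`, the inclusion–exclusion sum `m > 20`, unless
forced.  The tuple-counting cross-check is applied to corpus instances with
at most 6 maximal chains (k ≤ 3), the minimal-cover cross-checks to
instances with at most 14.

## Known limitations

* The exact cover routines are exponential in `m` by nature; the guards are
  honest refusals, not silent truncation.
* Minimal-cover enumeration materialises the essential chains before
  backtracking; it is not an anytime stream for very large chain families.
* No handling of noisy or partially observed matrices, no weighted covers,
  no node-induced chain subgraphs, and no special-cased polynomial classes
  (convex/chordal bipartite), which CI graphs do not fall into anyway.
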