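# Methods

This note records the model, the algorithms, and the deliberate design
decisions behind `rnatrees`.

## Model

An RNA secondary structure of length `n` is a set of base pairs `(i, j)`,
`1 <= i < j <= n`, that is non-crossing (for two pairs, either one nests
strictly inside the other or they are disjoint) and in which each position
participates in at most one pair. A minimum hairpin size `theta` requires
`j - i - 1 >= theta` for every pair; the library default is `theta = 3`,
matching the steric constraint commonly used for folded RNA.

Every structure is represented as an ordered rooted tree over the extended
leafset `[0, n+1]`:

* leaves are the integer positions `0, 1, ..., n+1`, in order;
* each base pair `(i, j)` is an internal node whose leftmost and rightmost
  leaf descendants are exactly `i` and `j`;
* a fictive root `(0, n+1)` closes the tree.

Two derived node attributes drive everything else:

* the **descendant leafset** `DL(x) = [i, j]`, the interval of leaves below
  the internal node `x = (i, j)` — under this representation a node *is* its
  descendant leafset, so set operations on internal-node sets are set
  operations on DLs;
* the **internal leafset** `IL(x)`, the set of leaf children of `x` — the
  loop enclosed by the pair (or by the fictive root). The internal leafsets
  of a tree form a *structural partition* of `[0, n+1]`: blocks of size at
  least two, mutually non-crossing, with `0` and `n+1` in the same block.
  Conversely every such partition assembles into exactly one RNA tree
  (`tree_from_structural_partition`).

## Distances

* **Base-pair / Robinson-Foulds distance.** `bp_distance` is the symmetric
  difference of the base-pair sets; `rf_distance` is the symmetric
  difference of the internal-node (DL) sets. Because a node is identified
  with its base pair, the two are equal; the test suite checks the identity
  on random pairs.
* **Internal-leafset distance.** `il_distance` is the symmetric difference
  of the IL multiset (each tree's ILs are pairwise distinct, so plain sets
  suffice). It is a metric and refines RF: trees at RF distance zero are
  identical, and IL separates trees that share base pairs but arrange
  unpaired positions differently.
* **Tree edit distance.** `tree_edit_distance(T1, T2, cost)` minimizes,
  over order- and nesting-preserving partial bijections `M` between
  internal nodes, `sum(cost over M) + |I1| + |I2| - 2|M|`. The *relaxed*
  cost `c((i1,j1),(i2,j2)) = |i1-i2| + |j1-j2|` gives `re_distance`; the
  *prohibitive* cost `2(n+2) + 1` makes any relabeling more expensive than
  a delete-insert pair, collapsing the edit distance to the base-pair
  distance (tested as an invariant).

  **Design decision.** The edit distance is computed with a memoized
  ordered-forest recursion (rightmost-root decomposition) rather than the
  array-based Zhang-Shasha tableau. The forests that arise are small
  (internal nodes only, not positions), memoization keeps the complexity
  polynomial in the number of base pairs, and the recursion yields the
  optimal mapping by direct backtrace. Ties prefer matching over
  delete/insert so reported mappings are maximal among optima.

## Medians

For trees `T_1..T_p`, the median problem asks for `M` minimizing
`Mcost(M) = sum_k d(M, T_k)`, possibly under a constraint:

* **NC** — `M` may be any RNA tree (only non-crossing);
* **ILC** — every internal leafset of `M` must appear in some input tree;
* **DLC** — every descendant leafset of `M` must appear in some input tree.

Implemented exact solvers:

* `rf_median` (RF, NC and DLC): the majority-rule tree. A DL is kept iff it
  occurs in more than `p/2` inputs; majority DLs are pairwise non-crossing,
  so they assemble into a tree. The same tree is optimal under DLC because
  it only uses input DLs.
* `il_ilc_median` (IL, ILC): by the structural-partition correspondence,
  minimizing `Mcost` is equivalent (up to the additive constant
  `sum_k |IL(T_k)|`) to choosing a structural partition minimizing the sum
  of per-block costs `cost(I) = p - 2 * occ(I)`, where `occ(I)` counts
  inputs containing `I` as an internal leafset. With candidate blocks
  restricted to input ILs, an interval dynamic program over `c[i, j]`
  (best cost of partitioning leaves `i..j` given that `i` starts a block)
  solves this exactly.
* `rf_ilc_median` (RF, ILC): the same partition DP with the block cost
  `p - 2 * #{k : (min I, max I) is a node of T_k}`, since choosing block
  `I` places the base pair `(min I, max I)` in the median.
* `il_nc_median` (IL, NC): extends the ILC DP with a second case that
  builds a *new* block from `i`, a chosen partner `k`, and everything in
  `(k, j]` not covered by recursively partitioned "gap" intervals. The best
  set of disjoint gap intervals is a maximum-weight independent set of
  intervals (`mwis_intervals`, solved by the classical sort-plus-binary-
  search DP), using interval values `chat[u, v] = c[u, v] - (v - u + 1)`
  (partition cost minus the saving from removing those leaves from the
  block).

  **Design decision (interval family).** The gap intervals allowed inside
  a new block spanning `[k+1, j]` are taken with *inclusive* bounds — a
  gap may start at `k+1` or end at `j`. A strictly interior family is not
  complete: optimal medians can require a gap flush against either end of
  the block. The unit tests compare against brute-force enumeration over
  all trees, which pinned this down. At the top level the rightmost gap is
  capped so that leaf `n+1` stays in the block containing leaf `0`, as the
  fictive root requires.

The RE (relaxed tree edit) median is not implemented; its complexity is
open and the CLI reports it as such.

## Small parsimony

Given a phylogeny `P` with structures at the leaves, assign trees to
internal nodes minimizing the sum of distances along branches (`SPcost`).

* `fitch_hartigan_rf` — exact for RF under NC. Each candidate DL (the
  union of input DLs) is an independent presence/absence character solved
  by the two-pass Fitch-Hartigan procedure on a (possibly multifurcating)
  rooted phylogeny; root ties resolve to absence, so reconstructions are
  conservative about base pairs. Selected DLs are conflict-free at every
  node and assemble into trees; the solution also satisfies DLC.
* `restricted_assignment` — the Sankoff dynamic program over the candidate
  set consisting of the distinct input trees, exact within that restricted
  space for any metric (RF, IL, RE).
* `median_local_search` — starts from the restricted assignment, then
  sweeps internal nodes in postorder, replacing each non-root node's tree
  by a median of its neighbors' trees (using the matching exact median
  solver for the chosen metric/constraint) whenever that strictly lowers
  the total cost, until a full sweep makes no improvement. The SP cost is
  maintained incrementally and never increases.

Exact small parsimony under IL or RE, and medians under DLC for IL, are
open problems and deliberately out of scope.

## Simulation

`count_structures(m, theta)` computes the number `S(m)` of structures of
length `m` via `S[m] = S[m-1] + sum_{j=theta+2}^{m} S[j-2] * S[m-j]` with
`S[0..theta+1] = 1`, in exact integer arithmetic (Python bigints; the
counts grow exponentially and must not be rounded).
`sample_uniform_structure` draws exactly uniformly by backtracking through
the same recurrence, choosing each case with probability proportional to
its count using `random.Random.randrange` over the integer totals — no
floating point enters the sampler. Uniformity is verified by a chi-square
test against full enumeration of the sample space.

`random_instance(height, m, theta, rng)` builds a complete binary phylogeny
(`2^height` leaves) and attaches independent uniform structures to the
leaves. Defaults are height 5, length 100, `theta = 3` — the regime used by
the bundled experiment script. Leaf structures are independent draws;
simulating evolution *along* the branches (indels, a substitution model)
is out of scope.

## Preprocessing

Seed alignments (Stockholm with a `#=GC SS_cons` line) become gap-free
equal-length structure sets in two steps: the consensus is projected onto
each row, keeping a pair only when both characters form a Watson-Crick or
wobble pair and neither is a gap; then every column gapped in *any* row is
deleted and positions renumbered, with pairs that lose one endpoint
becoming unpaired. WUSS bracket families are normalized to one nested
family and pseudoknot letters are treated as unpaired; crossing pairs
after normalization are rejected.

## Numerical and implementation choices

* All distances, costs, and counts are exact integers; the only sentinel
  is `INF = 10**9` for infeasible DP cells, chosen far above any reachable
  cost (costs are bounded by `p * (n + 2)` for the sizes the DPs accept)
  while staying safely summable.
* Standard formats go through established parsers — `dendropy` for Newick
  and Biopython for Stockholm — wrapped behind this package's API;
  dot-bracket parsing, the distances, and the dynamic programs are
  implemented here because they are the substance of the library.
* Determinism: every stochastic entry point takes an explicit seed or
  `random.Random`; tie-breaks in solvers are fixed (lowest index /
  first appearance), so identical inputs give identical outputs.

## Limitations

Pseudoknots are rejected by construction. Gapped structures must be
projected before any tree computation. The RE median, exact IL/RE small
parsimony, and IL-DLC medians are open problems and not provided.
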