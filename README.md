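# rnatrees

Median and small parsimony computations on RNA secondary structures
represented as ordered trees.

## Background

An RNA secondary structure of length `n` is a non-crossing set of base
pairs. Such a structure is equivalent to an ordered rooted tree over the
leafset `{0, 1, ..., n+1}`: each base pair `(i, j)` becomes an internal
node whose leftmost and rightmost leaf descendants are `i` and `j`, and a
fictive root pairs `0` with `n+1`. Two node attributes carry the
comparative signal: the **descendant leafset** (the interval of positions
enclosed by a pair) and the **internal leafset** (the loop of positions
immediately inside a pair).

Given several structures of equal length — for instance, homologous RNAs
from a gap-free projection of a family alignment — two ancestral-inference
problems arise:

* the **median problem**: find one structure minimizing the total distance
  to the inputs;
* the **small parsimony problem**: given a phylogeny with structures at
  the leaves, assign structures to internal nodes minimizing the total
  distance along branches.

`rnatrees` provides three tree distances — base-pair / Robinson-Foulds
(RF), internal-leafset (IL), and tree edit with a relaxed cost (RE) —
together with exact polynomial median solvers (RF unconstrained, and
RF/IL restricted or not to input internal leafsets), an exact RF small
parsimony solver based on per-leafset Fitch-Hartigan reconstruction, and
two general heuristics (restricted Sankoff assignment and median-based
local search). A uniform sampler over structures with a minimum hairpin
size supports simulation studies. See [docs/methods.md](docs/methods.md)
for the algorithms, constraints, and design decisions.

## Worked example

Three structures of length 7, FASTA-style dot-bracket in `toy.db`:

```
>a
((...))
>b
((...))
>c
(.....)
```

Pairwise IL distance matrix and the IL median constrained to input loops
(ILC):

```
$ rnatrees distance -i toy.db --metric il
	a	b	c
a	0	0	3
b	0	0	3
c	3	3	0

$ rnatrees median -i toy.db --metric il --constraint ilc
((...))
Mcost	3
```

Small parsimony on a four-leaf phylogeny (`phylo.nwk` containing
`((A,B),(C,D));`, leaves `A,B` = `((...))` and `C,D` = `(.....)` in
`leaves.db`), solved exactly under RF:

```
$ rnatrees smallparsimony -i leaves.db -t phylo.nwk --solver exact --report
((A,B)N1,(C,D)N2)N3;
N1	((...))
N2	(.....)
N3	(.....)
SPcost	1
node	base_pairs
N1	2
N2	1
N3	1
```

The root reconstruction keeps only the pair present on both sides; the
tie on the inner pair resolves to absence, which is why exact RF
reconstructions are conservative about base pairs.

The same computations from Python:

```python
from rnatrees import (parse_dotbracket, structure_to_tree, rf_distance,
                      il_distance, il_ilc_median, count_structures)

T1 = structure_to_tree(parse_dotbracket("((...))"))
T2 = structure_to_tree(parse_dotbracket("(.....)"))
print("internal nodes of T1:", sorted(T1.internal_nodes))
print("rf:", rf_distance(T1, T2), " il:", il_distance(T1, T2))
median, mcost = il_ilc_median([T1, T1, T2])
print("median:", median.to_dotbracket(), " Mcost:", mcost)
print("count_structures(10, 3):", count_structures(10, 3))
```

prints

```
internal nodes of T1: [(0, 8), (1, 7), (2, 6)]
rf: 1  il: 3
median: ((...))  Mcost: 3
count_structures(10, 3): 65
```

Simulated instances are exactly reproducible from a seed:

```
$ rnatrees simulate --height 2 --length 20 --theta 3 --seed 7 \
      --out-structures sim.db --out-newick sim.nwk
wrote 4 structures to sim.db
wrote phylogeny to sim.nwk
```

`preprocess` turns a Stockholm alignment with a `#=GC SS_cons` consensus
line into gap-free per-sequence dot-bracket structures (invalid pairs
dropped per sequence, gapped columns removed).

## Scope

Pseudoknots are rejected; structures must be gap-free and equal-length
before tree computations (use `preprocess`). The RE median and exact
IL/RE small parsimony are open problems and are reported as such by the
CLI rather than approximated silently.
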