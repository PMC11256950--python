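"""Small parsimony on a phylogeny of RNA structures.

Given a rooted (possibly multifurcating) phylogeny whose leaves carry RNA
trees on a common leafset, assign an RNA tree to every internal node so that
the sum of a tree distance over the phylogeny's edges (the SP cost) is
minimized.

Solvers:

* :func:`fitch_hartigan_rf` — exact for the RF distance, unconstrained
  (and the result automatically satisfies the DLC constraint): each
  candidate DL is treated as an independent presence/absence character and
  reconstructed with the Fitch-Hartigan two-pass algorithm, resolving root
  ties to absence; the selected DLs at each node are conflict-free and
  assemble into a tree.
* :func:`restricted_assignment` — exact under the restriction that every
  ancestor is assigned one of the distinct leaf trees (Sankoff-style
  dynamic program over the candidate set); works for any of the three
  metrics and serves both as an initializer and as the RE heuristic.
* :func:`median_local_search` — the classical median-based heuristic:
  start from the restricted assignment, then repeatedly replace a non-root
  internal node's tree by the median of its neighbors' trees whenever that
  strictly lowers the SP cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Optional, Sequence

from .core import RnaTree, tree_from_dls
from .distances import metric_function, rf_distance
from .medians import il_ilc_median, il_nc_median, rf_ilc_median, rf_median

__all__ = [
    "PhyloNode",
    "Phylogeny",
    "SpAssignment",
    "sp_cost",
    "fitch_hartigan_rf",
    "restricted_assignment",
    "median_local_search",
]


@dataclass(eq=False)
class PhyloNode:
    name: Optional[str] = None
    children: list["PhyloNode"] = field(default_factory=list)
    parent: Optional["PhyloNode"] = None
    edge_length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<PhyloNode {self.name or '?'} {kind}>"


class Phylogeny:
    """Rooted phylogeny with uniquely named leaves.

    Branch lengths, when present in the source Newick, are stored but unused
    by the parsimony algorithms (all edges count equally).
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if not names:
            raise ValueError("phylogeny has no leaves")
        if any(name is None for name in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        for node in self.postorder():
            for child in node.children:
                child.parent = node
        self.root.parent = None

    def postorder(self) -> Iterator[PhyloNode]:
        stack: list[tuple[PhyloNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[PhyloNode]:
        return [v for v in self.postorder() if v.is_leaf]

    def internal_nodes(self) -> list[PhyloNode]:
        """Internal nodes in postorder (root last)."""
        return [v for v in self.postorder() if not v.is_leaf]

    def edges(self) -> list[tuple[PhyloNode, PhyloNode]]:
        return [
            (v.parent, v) for v in self.postorder() if v.parent is not None
        ]

    @property
    def num_leaves(self) -> int:
        return len(self.leaves())


@dataclass
class SpAssignment:
    """Trees assigned to the internal nodes of a phylogeny, with SP cost."""

    trees: dict[PhyloNode, RnaTree]
    sp_cost: float


def _leaf_tree(leaf: PhyloNode, leaf_trees: Mapping[str, RnaTree]) -> RnaTree:
    try:
        return leaf_trees[leaf.name]
    except KeyError:
        raise KeyError(f"no structure given for leaf {leaf.name!r}") from None


def _check_leafsets(trees) -> None:
    ns = {t.n for t in trees}
    if len(ns) > 1:
        raise ValueError(f"leaf trees have different lengths: {sorted(ns)}")


def sp_cost(
    phylo: Phylogeny,
    leaf_trees: Mapping[str, RnaTree],
    assignment: Mapping[PhyloNode, RnaTree],
    metric: str,
) -> float:
    """Sum of the metric over the phylogeny's edges under ``assignment``."""
    fn = metric_function(metric)

    def tree_at(v: PhyloNode) -> RnaTree:
        if v.is_leaf:
            return _leaf_tree(v, leaf_trees)
        if v not in assignment:
            raise KeyError(f"internal node {v.name or v!r} has no assigned tree")
        return assignment[v]

    return sum(fn(tree_at(u), tree_at(v)) for u, v in phylo.edges())


def fitch_hartigan_rf(
    phylo: Phylogeny, leaf_trees: Mapping[str, RnaTree]
) -> SpAssignment:
    """Exact RF small parsimony via per-DL Fitch-Hartigan reconstruction.

    Every DL occurring in some leaf tree is scored as a 0/1 character; DLs
    absent from all leaves are never gained, so they need not be enumerated.
    Root ties resolve to 0 (absence), which keeps the per-node DL sets
    conflict-free so each assembles into a tree.
    """
    leaves = phylo.leaves()
    trees = [_leaf_tree(v, leaf_trees) for v in leaves]
    _check_leafsets(trees)
    n = trees[0].n
    candidates = sorted(set().union(*(t.internal_nodes for t in trees)))

    order = list(phylo.postorder())
    selected: dict[PhyloNode, set] = {
        v: set() for v in order if not v.is_leaf
    }
    for dl in candidates:
        # bottom-up: Hartigan vote counts over children
        vu: dict[PhyloNode, frozenset[int]] = {}
        for v in order:
            if v.is_leaf:
                vu[v] = frozenset({int(dl in _leaf_tree(v, leaf_trees).internal_nodes)})
            else:
                votes = {0: 0, 1: 0}
                for child in v.children:
                    for s in vu[child]:
                        votes[s] += 1
                top = max(votes.values())
                vu[v] = frozenset(s for s in (0, 1) if votes[s] == top)
        # top-down: root ties -> 0; children keep the parent state when optimal
        states: dict[PhyloNode, int] = {}
        for v in reversed(order):
            if v.is_leaf:
                continue
            if v.parent is None:
                states[v] = 0 if 0 in vu[v] else 1
            else:
                s = states[v.parent]
                states[v] = s if s in vu[v] else next(iter(vu[v]))
            if states[v]:
                selected[v].add(dl)

    assignment = {
        v: tree_from_dls(dls | {(0, n + 1)}, n) for v, dls in selected.items()
    }
    cost = sp_cost(phylo, leaf_trees, assignment, "rf")
    return SpAssignment(trees=assignment, sp_cost=cost)


def restricted_assignment(
    phylo: Phylogeny, leaf_trees: Mapping[str, RnaTree], metric: str
) -> SpAssignment:
    """Optimal assignment drawing every ancestor from the distinct leaf trees.

    Classic bottom-up dynamic program over the candidate set with a
    precomputed pairwise distance matrix; ties resolve to the candidate of
    lowest index (candidates ordered by first appearance among the leaves).
    """
    leaves = phylo.leaves()
    trees = [_leaf_tree(v, leaf_trees) for v in leaves]
    _check_leafsets(trees)
    fn = metric_function(metric)

    candidates: list[RnaTree] = []
    index: dict[RnaTree, int] = {}
    for t in trees:
        if t not in index:
            index[t] = len(candidates)
            candidates.append(t)
    m = len(candidates)
    dmat = [[0.0] * m for _ in range(m)]
    for a in range(m):
        for b in range(a + 1, m):
            dmat[a][b] = dmat[b][a] = fn(candidates[a], candidates[b])

    # cost[v][c]: best cost of v's subtree edges when v is assigned candidate c
    cost: dict[PhyloNode, list[float]] = {}
    best_child: dict[tuple[PhyloNode, int], int] = {}
    for v in phylo.postorder():
        if v.is_leaf:
            continue
        row = [0.0] * m
        for child in v.children:
            if child.is_leaf:
                b = index[_leaf_tree(child, leaf_trees)]
                for c in range(m):
                    row[c] += dmat[c][b]
            else:
                child_row = cost[child]
                for c in range(m):
                    best, arg = None, -1
                    for b in range(m):
                        val = child_row[b] + dmat[c][b]
                        if best is None or val < best:
                            best, arg = val, b
                    row[c] += best
                    best_child[(child, c)] = arg
        cost[v] = row

    assignment: dict[PhyloNode, RnaTree] = {}
    root_row = cost[phylo.root]
    root_choice = min(range(m), key=lambda c: (root_row[c], c))
    chosen: dict[PhyloNode, int] = {phylo.root: root_choice}
    for v in reversed(list(phylo.postorder())):
        if v.is_leaf:
            continue
        if v.parent is not None:
            chosen[v] = best_child[(v, chosen[v.parent])]
        assignment[v] = candidates[chosen[v]]
    total = sp_cost(phylo, leaf_trees, assignment, metric)
    return SpAssignment(trees=assignment, sp_cost=total)


_MEDIAN_SOLVERS: dict[tuple[str, str], Callable[[Sequence[RnaTree]], tuple[RnaTree, int]]] = {
    ("rf", "nc"): rf_median,
    ("rf", "dlc"): rf_median,
    ("rf", "ilc"): rf_ilc_median,
    ("il", "ilc"): il_ilc_median,
    ("il", "nc"): il_nc_median,
}


def median_local_search(
    phylo: Phylogeny,
    leaf_trees: Mapping[str, RnaTree],
    metric: str,
    constraint: str,
    max_sweeps: int = 100,
) -> SpAssignment:
    """Median-based local search for small parsimony.

    Initializes with :func:`restricted_assignment`, then sweeps the non-root
    internal nodes in postorder: each node is offered the median (under the
    given metric and constraint) of its neighbors' current trees and updated
    only on strict SP-cost improvement, until a sweep changes nothing.
    """
    metric, constraint = metric.lower(), constraint.lower()
    try:
        solver = _MEDIAN_SOLVERS[(metric, constraint)]
    except KeyError:
        raise ValueError(
            f"no median solver for metric={metric!r}, constraint={constraint!r}"
        ) from None
    fn = metric_function(metric)
    init = restricted_assignment(phylo, leaf_trees, metric)
    assignment = dict(init.trees)
    total = init.sp_cost

    def tree_at(v: PhyloNode) -> RnaTree:
        return _leaf_tree(v, leaf_trees) if v.is_leaf else assignment[v]

    internal = [v for v in phylo.internal_nodes() if v.parent is not None]
    for _ in range(max_sweeps):
        improved = False
        for v in internal:
            neighbors = [tree_at(v.parent)] + [tree_at(c) for c in v.children]
            median, _ = solver(neighbors)
            old_local = sum(fn(tree_at(v), t) for t in neighbors)
            new_local = sum(fn(median, t) for t in neighbors)
            if new_local < old_local:
                assignment[v] = median
                total = total - old_local + new_local
                improved = True
        if not improved:
            break
    return SpAssignment(trees=assignment, sp_cost=total)
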