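"""Distances between RNA trees on a common leafset.

Three metrics are provided:

* **BP / RF** — the symmetric difference of the base-pair sets, equal to the
  Robinson-Foulds symmetric difference of descendant-leafset collections;
* **IL** — the symmetric difference of internal-leafset collections, which
  compares loops rather than individual pairs;
* **TE / RE** — the minimum cost of a *valid mapping*: an order- and
  nesting-preserving partial bijection between the internal-node sets, where
  each unmapped node costs 1 and each mapped couple costs ``c(x1, x2)``.
  The Relaxed-Edit distance is the TE distance under
  ``c*((i1,j1),(i2,j2)) = |i1-i2| + |j1-j2|``, which lets imperfectly
  aligned pairs map to each other.

Valid mappings are exactly the edit mappings of ordered trees, so the TE
distance is computed by an ordered-forest edit dynamic program (rightmost
root decomposition, memoized) with unit insertion/deletion cost, together
with a backtrace producing one optimal mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .core import RnaStructure, RnaTree, internal_leafsets

__all__ = [
    "TreeMapping",
    "bp_distance",
    "rf_distance",
    "il_distance",
    "tree_edit_distance",
    "re_distance",
    "relaxed_cost",
    "prohibitive_cost",
]

Node = tuple[int, int]
CostFn = Callable[[Node, Node], float]


@dataclass(frozen=True)
class TreeMapping:
    """A valid mapping between the internal-node sets of two trees.

    ``pairs`` lists the mapped couples ``((i1,j1), (i2,j2))``; ``cost`` is
    ``sum c(x1,x2) + |I(T1)| + |I(T2)| - 2 |pairs|``.
    """

    pairs: tuple[tuple[Node, Node], ...]
    cost: float


def _require_same_leafset(a, b) -> None:
    if a.n != b.n:
        raise ValueError(f"leafset mismatch: n={a.n} vs n={b.n}")


def bp_distance(R1: RnaStructure, R2: RnaStructure) -> int:
    """Size of the symmetric difference of the two pair sets."""
    _require_same_leafset(R1, R2)
    return len(R1.pairs ^ R2.pairs)


def rf_distance(T1: RnaTree, T2: RnaTree) -> int:
    """Robinson-Foulds distance: symmetric difference of DL collections.

    The DL of node ``(i, j)`` is the interval ``[i, j]``, so this is the
    symmetric difference of the internal-node sets.
    """
    _require_same_leafset(T1, T2)
    return len(T1.internal_nodes ^ T2.internal_nodes)


def il_distance(T1: RnaTree, T2: RnaTree) -> int:
    """Internal-Leafset distance: symmetric difference of IL collections."""
    _require_same_leafset(T1, T2)
    return len(internal_leafsets(T1) ^ internal_leafsets(T2))


def relaxed_cost(x1: Node, x2: Node) -> int:
    """Rename cost ``|i1-i2| + |j1-j2|`` of the Relaxed-Edit distance."""
    return abs(x1[0] - x2[0]) + abs(x1[1] - x2[1])


def prohibitive_cost(n: int) -> CostFn:
    """Rename cost 0 for identical pairs, otherwise too large to ever use.

    ``2(n+2)+1`` exceeds the cost of deleting and re-inserting every node,
    so a mapping of distinct pairs is never optimal and the TE distance
    collapses to the BP distance.
    """
    big = 2 * (n + 2) + 1

    def cost(x1: Node, x2: Node) -> int:
        return 0 if x1 == x2 else big

    return cost


class _ForestEdit:
    """Memoized ordered-forest edit distance over internal-node trees."""

    def __init__(self, T1: RnaTree, T2: RnaTree, cost: CostFn):
        self.cost = cost
        self.kids1 = T1._children
        self.kids2 = T2._children
        self.size1 = self._sizes(T1)
        self.size2 = self._sizes(T2)
        self.memo: dict = {}
        self.root1 = T1.root
        self.root2 = T2.root

    @staticmethod
    def _sizes(T: RnaTree) -> dict[Node, int]:
        sizes: dict[Node, int] = {}
        for node in sorted(T.internal_nodes, key=lambda p: p[1] - p[0]):
            sizes[node] = 1 + sum(sizes[c] for c in T._children[node])
        return sizes

    def _forest_size(self, f: tuple[Node, ...], sizes) -> int:
        return sum(sizes[t] for t in f)

    def dist(self, f1: tuple[Node, ...], f2: tuple[Node, ...]):
        """Min edit cost between forests plus the mapped couples attaining it."""
        key = (f1, f2)
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        if not f1 and not f2:
            result = (0, ())
        elif not f1:
            result = (self._forest_size(f2, self.size2), ())
        elif not f2:
            result = (self._forest_size(f1, self.size1), ())
        else:
            t1, t2 = f1[-1], f2[-1]
            c1, c2 = tuple(self.kids1[t1]), tuple(self.kids2[t2])
            # match rightmost roots
            d_rest, m_rest = self.dist(f1[:-1], f2[:-1])
            d_sub, m_sub = self.dist(c1, c2)
            best = d_rest + d_sub + self.cost(t1, t2)
            best_map = m_rest + m_sub + ((t1, t2),)
            # delete t1
            d_del, m_del = self.dist(f1[:-1] + c1, f2)
            if d_del + 1 < best:
                best, best_map = d_del + 1, m_del
            # insert t2
            d_ins, m_ins = self.dist(f1, f2[:-1] + c2)
            if d_ins + 1 < best:
                best, best_map = d_ins + 1, m_ins
            result = (best, best_map)
        self.memo[key] = result
        return result


def tree_edit_distance(
    T1: RnaTree, T2: RnaTree, cost: CostFn
) -> tuple[float, TreeMapping]:
    """Minimum cost of a valid mapping between ``T1`` and ``T2``.

    Returns the optimal value and one mapping attaining it.  Ties are broken
    deterministically (match preferred over deletion over insertion).
    """
    _require_same_leafset(T1, T2)
    solver = _ForestEdit(T1, T2, cost)
    value, pairs = solver.dist((T1.root,), (T2.root,))
    return value, TreeMapping(pairs=tuple(sorted(pairs)), cost=value)


def re_distance(T1: RnaTree, T2: RnaTree) -> tuple[int, TreeMapping]:
    """Relaxed-Edit distance: tree edit distance under :func:`relaxed_cost`."""
    return tree_edit_distance(T1, T2, relaxed_cost)


def distance_matrix(
    trees: Sequence[RnaTree], metric: str
) -> list[list[float]]:
    """Symmetric pairwise distance matrix under ``metric`` in {rf, il, re}."""
    fn = metric_function(metric)
    p = len(trees)
    mat = [[0.0] * p for _ in range(p)]
    for i in range(p):
        for j in range(i + 1, p):
            mat[i][j] = mat[j][i] = fn(trees[i], trees[j])
    return mat


def metric_function(metric: str) -> Callable[[RnaTree, RnaTree], float]:
    """Resolve a metric name to a tree-distance function returning a number."""
    metric = metric.lower()
    if metric == "rf":
        return rf_distance
    if metric == "il":
        return il_distance
    if metric == "re":
        return lambda a, b: re_distance(a, b)[0]
    raise ValueError(f"unknown metric {metric!r} (expected rf, il or re)")
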