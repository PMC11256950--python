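"""Independent brute-force oracles used to validate the polynomial algorithms.

Everything here recomputes quantities from first principles (exhaustive
enumeration over strings, mappings, partitions or assignments) and must not
depend on the dynamic programs under test.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

from rnatrees.core import (
    RnaTree,
    il_conflict,
    parse_dotbracket,
    structure_to_tree,
    tree_from_structural_partition,
)


def dotbracket_pairs(s: str):
    """Pair set of a balanced string, or None if unbalanced (no theta check)."""
    stack, pairs = [], []
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                return None
            pairs.append((stack.pop(), pos))
    return None if stack else pairs


def all_structures_filter(m: int, theta: int) -> list[str]:
    """All admissible strings of length m by filtering the full 3^m product."""
    out = []
    for chars in itertools.product("(.)", repeat=m):
        s = "".join(chars)
        pairs = dotbracket_pairs(s)
        if pairs is None:
            continue
        if all(j - i - 1 >= theta for i, j in pairs):
            out.append(s)
    return out


def all_trees(n: int, theta: int = 0) -> list[RnaTree]:
    """Every RNA tree with leafset [0, n+1] (brute force for small n)."""
    return [
        structure_to_tree(parse_dotbracket(s))
        for s in all_structures_filter(n, theta)
    ]


# ---------------------------------------------------------------- distances

def _precedes(a, b) -> bool:
    """Strict ancestor relation between internal nodes (nesting)."""
    return a[0] < b[0] and b[1] < a[1]


def brute_force_ted(T1: RnaTree, T2: RnaTree, cost) -> float:
    """Minimum valid-mapping cost by exhaustive enumeration.

    Valid mappings are monotone in postorder, so it suffices to pair
    equal-size postorder-sorted subsets and check nesting preservation.
    Only feasible for trees with few internal nodes.
    """
    def postorder_key(node):
        return (node[1], -node[0])

    I1 = sorted(T1.internal_nodes, key=postorder_key)
    I2 = sorted(T2.internal_nodes, key=postorder_key)
    base = len(I1) + len(I2)
    best = float(base)  # empty mapping
    for size in range(1, min(len(I1), len(I2)) + 1):
        for A in itertools.combinations(I1, size):
            for B in itertools.combinations(I2, size):
                ok = all(
                    _precedes(A[a], A[b]) == _precedes(B[a], B[b])
                    for a in range(size)
                    for b in range(size)
                    if a != b
                )
                if not ok:
                    continue
                val = sum(cost(x, y) for x, y in zip(A, B)) + base - 2 * size
                best = min(best, val)
    return best


# ------------------------------------------------------------------ medians

def brute_force_median(
    trees: Sequence[RnaTree], dist, candidates: Sequence[RnaTree]
):
    """(min Mcost, set of optimal candidates) over an explicit candidate list."""
    costs = [(sum(dist(t, c) for t in trees), c) for c in candidates]
    best = min(v for v, _ in costs)
    return best, [c for v, c in costs if v == best]


def restricted_partitions(n: int, blocks: Iterable[frozenset[int]]):
    """All structural partitions of [0, n+1] drawn from the given blocks,
    with 0 and n+1 in the same block (i.e. the IL set of some tree)."""
    blocks = sorted({frozenset(b) for b in blocks}, key=lambda b: sorted(b))
    top = n + 1
    results = []

    def extend(chosen: list, covered: frozenset):
        if len(covered) == top + 1:
            results.append(list(chosen))
            return
        nxt = min(set(range(top + 1)) - set(covered))
        for b in blocks:
            if nxt not in b or min(b) != nxt:
                continue
            if b & covered:
                continue
            if any(il_conflict(b, c) for c in chosen):
                continue
            chosen.append(b)
            extend(chosen, covered | b)
            chosen.pop()

    extend([], frozenset())
    out = []
    for part in results:
        root_block = next(b for b in part if 0 in b)
        if top in root_block:
            out.append(part)
    return out


def brute_force_partition_median(
    n: int, blocks: Iterable[frozenset[int]], block_cost
):
    """(min total block cost, optimal trees) over restricted partitions."""
    parts = restricted_partitions(n, blocks)
    assert parts, "no feasible restricted partition"
    scored = [(sum(block_cost(b) for b in part), part) for part in parts]
    best = min(v for v, _ in scored)
    trees = [
        tree_from_structural_partition(part) for v, part in scored if v == best
    ]
    return best, trees


# --------------------------------------------------------------- parsimony

def brute_force_sp(phylo, leaf_trees, dist, candidates: Sequence[RnaTree]):
    """Exhaustive minimum SP cost over all internal-node assignments."""
    internal = phylo.internal_nodes()
    best = None
    for combo in itertools.product(candidates, repeat=len(internal)):
        assigned = dict(zip(internal, combo))

        def tree_at(v):
            return leaf_trees[v.name] if v.is_leaf else assigned[v]

        total = sum(dist(tree_at(u), tree_at(v)) for u, v in phylo.edges())
        if best is None or total < best:
            best = total
    return best
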