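"""Median solvers for sets of RNA trees on a common leafset.

Given trees ``T_1..T_p``, a median minimizes ``Mcost(T) = sum_k D(T_k, T)``
under a metric D (RF or IL here) and a constraint on the output tree:

* **NC** — unconstrained;
* **DLC** — every DL of the output occurs in some input tree;
* **ILC** — every IL of the output occurs in some input tree.

Solvers:

* :func:`rf_median` — majority-rule consensus: the tree displaying exactly
  the DLs present in strictly more than half of the inputs is an optimal
  RF_NC median and automatically satisfies DLC.  O(p n^2).
* :func:`il_ilc_median` — dynamic program over *structural partitions*
  (partitions of the leafset into non-conflicting blocks of size >= 2,
  which are in bijection with RNA trees) restricted to input ILs, using the
  per-block cost ``cost_IL(I) = #{k: I not in IL(T_k)} - #{k: I in IL(T_k)}``
  whose sum equals the IL Mcost up to the constant ``sum_k |IL(T_k)|``.
  O(p n^3).
* :func:`il_nc_median` — the unconstrained generalization: a block absent
  from every input costs exactly ``p``, so the DP additionally minimizes,
  for every way of starting a new block ``{i, k, ...}``, over independent
  sets of "gap" intervals weighted by the sub-problem costs — a maximum
  weighted independent set on an interval graph.  O(p n^5) worst case.
* :func:`rf_ilc_median` — the ILC DP with the per-block cost counting
  base-pair occurrences instead of IL occurrences, so the partition cost
  tracks the RF Mcost up to a constant.

RE medians are an open problem and are not provided.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

from .core import (
    RnaTree,
    gaps,
    internal_leafsets,
    tree_from_dls,
    tree_from_structural_partition,
)
from .distances import il_distance, metric_function, rf_distance

__all__ = [
    "rf_median",
    "il_cost",
    "il_ilc_median",
    "il_nc_median",
    "rf_ilc_median",
    "mwis_intervals",
    "median_cost",
]

INF = 10**9  # safely above any reachable partition cost p * (n + 2)

IL = frozenset


def _common_n(trees: Sequence[RnaTree]) -> int:
    if not trees:
        raise ValueError("median of an empty set of trees")
    n = trees[0].n
    for t in trees:
        if t.n != n:
            raise ValueError("input trees have different leafsets")
    return n


def median_cost(candidate: RnaTree, trees: Sequence[RnaTree], metric: str) -> float:
    """``sum_k D(T_k, candidate)`` under the named metric (rf, il or re)."""
    fn = metric_function(metric)
    return sum(fn(t, candidate) for t in trees)


def rf_median(trees: Sequence[RnaTree]) -> tuple[RnaTree, int]:
    """Majority-rule consensus: optimal RF_NC (and RF_DLC) median.

    Keeps exactly the DLs displayed by strictly more than half of the input
    trees; these are always conflict-free, so the tree exists and is unique.
    """
    n = _common_n(trees)
    counts: dict[tuple[int, int], int] = {}
    for t in trees:
        for node in t.internal_nodes:
            counts[node] = counts.get(node, 0) + 1
    half = len(trees) / 2
    majority = {node for node, c in counts.items() if c > half}
    majority.add((0, n + 1))
    median = tree_from_dls(majority, n)
    return median, sum(rf_distance(t, median) for t in trees)


def il_cost(I: Iterable[int], trees: Sequence[RnaTree]) -> int:
    """Per-block cost ``#{k: I not in IL(T_k)} - #{k: I in IL(T_k)}``.

    Negative for ILs present in more than half the inputs; ``p`` for ILs
    absent from all of them.
    """
    I = frozenset(I)
    occ = sum(I in internal_leafsets(t) for t in trees)
    return len(trees) - 2 * occ


def mwis_intervals(
    intervals: Sequence[tuple[int, int, float]]
) -> tuple[float, list[tuple[int, int]]]:
    """Maximum weighted independent set of closed integer intervals.

    ``intervals`` holds ``(lo, hi, weight)`` triples; two intervals conflict
    when they share an integer point.  The empty set (value 0) is always
    allowed, so non-positive weights are never forced.
    """
    items = sorted(
        ((lo, hi, w) for lo, hi, w in intervals if w > 0), key=lambda x: x[1]
    )
    if not items:
        return 0.0, []
    best: list[float] = [0.0] * (len(items) + 1)  # best over first m items
    choice: list[tuple[int, int] | None] = [None] * (len(items) + 1)
    prev: list[int] = [0] * (len(items) + 1)
    rights = [it[1] for it in items]
    import bisect

    for m, (lo, hi, w) in enumerate(items, start=1):
        # last item (by index) whose right end is < lo
        q = bisect.bisect_left(rights, lo, 0, m - 1)
        take = best[q] + w
        if take > best[m - 1]:
            best[m] = take
            choice[m] = (lo, hi)
            prev[m] = q
        else:
            best[m] = best[m - 1]
            choice[m] = None
            prev[m] = m - 1
    chosen = []
    m = len(items)
    while m > 0:
        if choice[m] is not None:
            chosen.append(choice[m])
        m = prev[m]
    chosen.reverse()
    return best[-1], chosen


def _collect_ils(trees: Sequence[RnaTree]) -> dict[IL, int]:
    counts: dict[IL, int] = {}
    for t in trees:
        for I in internal_leafsets(t):
            counts[I] = counts.get(I, 0) + 1
    return counts


def _canonical_key(I: IL) -> tuple:
    return tuple(sorted(I))


def _ilc_partition_dp(
    n: int, candidates: dict[IL, float]
) -> tuple[float, list[IL]]:
    """Minimum-cost structural partition of ``[0, n+1]`` using only the
    candidate blocks, with the given per-block costs.

    ``c[i][j]`` is the best cost of partitioning ``[i, j]`` into candidate
    blocks; the block containing ``i`` is enumerated, its gaps and the
    trailing interval after its maximum are optimized recursively.
    """
    # index candidates by their minimum element, in canonical order for ties
    by_min: dict[int, list[tuple[IL, float, int, list[tuple[int, int]]]]] = {}
    for I in sorted(candidates, key=_canonical_key):
        by_min.setdefault(min(I), []).append(
            (I, candidates[I], max(I), gaps(I))
        )

    top = n + 1
    c: dict[tuple[int, int], float] = {}
    back: dict[tuple[int, int], tuple[IL, int, list[tuple[int, int]]]] = {}

    def cval(i: int, j: int) -> float:
        if j < i:
            return 0.0
        return c.get((i, j), INF)

    for length in range(1, top + 1):
        for i in range(0, top - length + 1):
            j = i + length
            best, best_choice = INF, None
            for I, cost, mx, gp in by_min.get(i, ()):
                if mx > j:
                    continue
                total = cost
                for (x, y) in gp:
                    total += cval(x, y)
                    if total >= INF:
                        break
                else:
                    total += cval(mx + 1, j)
                if total < best:
                    best, best_choice = total, (I, mx, gp)
            if best_choice is not None:
                c[(i, j)] = best
                back[(i, j)] = best_choice

    if (0, top) not in c:
        raise ValueError("no structural partition exists over the candidate blocks")

    blocks: list[IL] = []

    def reconstruct(i: int, j: int) -> None:
        if j < i:
            return
        I, mx, gp = back[(i, j)]
        blocks.append(I)
        for (x, y) in gp:
            reconstruct(x, y)
        reconstruct(mx + 1, j)

    reconstruct(0, top)
    return c[(0, top)], blocks


def il_ilc_median(trees: Sequence[RnaTree]) -> tuple[RnaTree, int]:
    """IL median constrained to input ILs, by dynamic programming.

    Always feasible: each input tree's own IL collection is a structural
    partition.  Returns the median tree and its IL Mcost.
    """
    n = _common_n(trees)
    counts = _collect_ils(trees)
    p = len(trees)
    candidates = {I: float(p - 2 * occ) for I, occ in counts.items()}
    _, blocks = _ilc_partition_dp(n, candidates)
    median = tree_from_structural_partition(blocks)
    return median, sum(il_distance(t, median) for t in trees)


def rf_ilc_median(trees: Sequence[RnaTree]) -> tuple[RnaTree, int]:
    """RF median constrained to input ILs.

    Same DP as :func:`il_ilc_median` with the per-block cost counting
    occurrences of the block's base pair ``(min I, max I)`` in the inputs,
    so the partition cost equals the RF Mcost up to ``sum_k |I(T_k)|``.
    """
    n = _common_n(trees)
    counts = _collect_ils(trees)
    p = len(trees)
    candidates = {}
    for I in counts:
        bp = (min(I), max(I))
        occ = sum(bp in t.internal_nodes for t in trees)
        candidates[I] = float(p - 2 * occ)
    _, blocks = _ilc_partition_dp(n, candidates)
    median = tree_from_structural_partition(blocks)
    return median, sum(rf_distance(t, median) for t in trees)


def il_nc_median(trees: Sequence[RnaTree]) -> tuple[RnaTree, int]:
    """Unconstrained IL median, by dynamic programming.

    ``chat[i][j]`` is the minimum cost of any structural partition of
    ``[i, j]``.  The block I containing ``i`` is either an input IL
    (enumerated as in the ILC DP) or a new block of cost ``p``; in the
    latter case we choose its second element ``k``, partition the full gap
    ``[i+1, k-1]`` recursively, and choose the remaining gaps inside
    ``[k+1, j]`` as a maximum "weight" (most negative total cost) set of
    disjoint intervals — positions not covered by a chosen gap belong to I.
    """
    n = _common_n(trees)
    p = len(trees)
    counts = _collect_ils(trees)
    input_cost = {I: float(p - 2 * occ) for I, occ in counts.items()}
    by_min: dict[int, list[tuple[IL, float, int, list[tuple[int, int]]]]] = {}
    for I in sorted(input_cost, key=_canonical_key):
        by_min.setdefault(min(I), []).append(
            (I, input_cost[I], max(I), gaps(I))
        )

    top = n + 1
    chat: dict[tuple[int, int], float] = {}
    # W[(a, b)]: best (most negative) total chat over disjoint subintervals of [a, b]
    W: dict[tuple[int, int], float] = {}

    def cv(i: int, j: int) -> float:
        if j < i:
            return 0.0
        return chat.get((i, j), INF)

    def wv(a: int, b: int) -> float:
        # a single position cannot host a block (size >= 2), so W is 0 there
        if b <= a:
            return 0.0
        return W[(a, b)]

    def best_input_block(i: int, j: int):
        best, best_choice = INF, None
        for I, cost, mx, gp in by_min.get(i, ()):
            if mx > j:
                continue
            total = cost
            for (x, y) in gp:
                total += cv(x, y)
                if total >= INF:
                    break
            else:
                total += cv(mx + 1, j)
            if total < best:
                best, best_choice = total, (I, mx, gp)
        return best, best_choice

    def best_new_block(i: int, j: int, *, gap_hi: int | None = None):
        """Best cost with a non-input block containing ``i``.

        ``gap_hi`` caps the right end of chosen gap intervals; the top-level
        call uses it to force ``j`` itself into the block (the root block of
        a tree must contain both boundary leaves).
        """
        hi = j if gap_hi is None else gap_hi
        best, best_k = INF, None
        for k in range(i + 1, j + 1):
            inner = cv(i + 1, k - 1)
            if inner >= INF:
                continue
            total = p + inner + wv(k + 1, hi)
            if total < best:
                best, best_k = total, k
        return best, best_k

    for length in range(1, top + 1):
        for i in range(0, top - length + 1):
            j = i + length
            if (i, j) != (0, top):
                c1, _ = best_input_block(i, j)
                c2, _ = best_new_block(i, j)
                val = min(c1, c2)
                if val < INF:
                    chat[(i, j)] = val
            # W over [a, b] = [i, j]: either skip j, or end an interval at j
            w = wv(i, j - 1)
            for u in range(i, j + 1):
                cu = cv(u, j)
                if cu < INF:
                    w = min(w, wv(i, u - 1) + cu)
            W[(i, j)] = w

    # top interval: the block containing 0 must also contain n+1 (trees only)
    c1_top, choice_top = best_input_block(0, top)
    if choice_top is not None and choice_top[1] != top:
        c1_top, choice_top = INF, None  # cannot happen for input ILs
    c2_top, _ = best_new_block(0, top, gap_hi=top - 1)
    chat[(0, top)] = min(c1_top, c2_top)

    blocks: list[IL] = []

    def reconstruct_w(a: int, b: int) -> list[tuple[int, int]]:
        """Disjoint intervals attaining W[a, b]."""
        if b < a:
            return []
        target = wv(a, b)
        if target == wv(a, b - 1):
            return reconstruct_w(a, b - 1)
        for u in range(a, b + 1):
            cu = cv(u, b)
            if cu < INF and wv(a, u - 1) + cu == target:
                return reconstruct_w(a, u - 1) + [(u, b)]
        raise AssertionError("W backtrace failed")

    def reconstruct(i: int, j: int, *, gap_hi: int | None = None) -> None:
        if j < i:
            return
        target = chat[(i, j)]
        c1, choice1 = best_input_block(i, j)
        if c1 == target and choice1 is not None:
            I, mx, gp = choice1
            blocks.append(I)
            for (x, y) in gp:
                reconstruct(x, y)
            reconstruct(mx + 1, j)
            return
        hi = j if gap_hi is None else gap_hi
        _, k = best_new_block(i, j, gap_hi=gap_hi)
        assert k is not None
        chosen = reconstruct_w(k + 1, hi)
        members = {i, k}
        covered = set()
        for (u, v) in chosen:
            covered.update(range(u, v + 1))
        members.update(q for q in range(k + 1, j + 1) if q not in covered)
        blocks.append(frozenset(members))
        reconstruct(i + 1, k - 1)
        for (u, v) in chosen:
            reconstruct(u, v)

    reconstruct(0, top, gap_hi=top - 1)
    median = tree_from_structural_partition(blocks)
    return median, sum(il_distance(t, median) for t in trees)
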