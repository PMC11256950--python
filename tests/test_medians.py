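"""Median solvers against brute-force enumeration."""

import random

import pytest

from rnatrees.core import (
    internal_leafsets,
    parse_dotbracket,
    structure_to_tree,
    tree_from_dls,
)
from rnatrees.distances import il_distance, rf_distance
from rnatrees.medians import (
    il_cost,
    il_ilc_median,
    il_nc_median,
    median_cost,
    mwis_intervals,
    rf_ilc_median,
    rf_median,
)

from conftest import random_tree
from oracles import (
    all_trees,
    brute_force_median,
    brute_force_partition_median,
)


def t(s):
    return structure_to_tree(parse_dotbracket(s))


TOY = [t("((...))"), t("((...))"), t("(.....)")]


def test_rf_median_toy():
    median, mcost = rf_median(TOY)
    assert median.to_dotbracket() == "((...))"
    assert mcost == 1


def test_rf_median_two_trees():
    median, mcost = rf_median([t("((...))"), t("(.....)")])
    assert median.to_dotbracket() == "(.....)"  # strict majority only
    assert mcost == 1


def test_rf_median_identical_inputs():
    median, mcost = rf_median([t("(.(...))")] * 4)
    assert median == t("(.(...))")
    assert mcost == 0


def test_il_cost_values():
    assert il_cost({0, 8}, TOY) == -3
    assert il_cost({1, 7}, TOY) == -1  # the bare loop {1,7} occurs in 2 of 3
    assert il_cost(frozenset(range(2, 7)), TOY) == -1  # in 2 of 3
    assert il_cost({3, 5}, TOY) == 3  # absent from all


def test_il_cost_constant_shift_identity():
    """sum il_cost over IL(M) + sum_k |IL(T_k)| == Mcost(M) for any M."""
    r = random.Random(23)
    for _ in range(20):
        trees = [random_tree(8, 0, r) for _ in range(3)]
        M = random_tree(8, 0, r)
        shift = sum(len(internal_leafsets(tr)) for tr in trees)
        total = sum(il_cost(I, trees) for I in internal_leafsets(M))
        assert total + shift == median_cost(M, trees, "il")


def test_il_ilc_median_toy():
    median, mcost = il_ilc_median(TOY)
    assert median.to_dotbracket() == "((...))"
    assert mcost == 3
    # partition cost relates to Mcost by the constant shift
    part_cost = sum(il_cost(I, TOY) for I in internal_leafsets(median))
    assert part_cost == -5


def test_il_ilc_median_single_tree():
    median, mcost = il_ilc_median([t("((..))..")])
    assert median == t("((..))..")
    assert mcost == 0


def test_il_ilc_two_trees():
    median, mcost = il_ilc_median([t("((...))"), t("(.....)")])
    assert mcost == 3
    part_cost = sum(
        il_cost(I, [t("((...))"), t("(.....)")]) for I in internal_leafsets(median)
    )
    assert part_cost == -2


def test_mwis_examples():
    assert mwis_intervals([(1, 3, 2), (2, 5, 3), (4, 6, 4)]) == (6, [(1, 3), (4, 6)])
    assert mwis_intervals([]) == (0, [])
    assert mwis_intervals([(1, 2, -1)]) == (0, [])


def test_mwis_brute_force():
    r = random.Random(29)
    import itertools

    for _ in range(40):
        items = []
        for _ in range(r.randint(0, 8)):
            lo = r.randint(0, 12)
            hi = r.randint(lo, 13)
            items.append((lo, hi, r.randint(-3, 5)))
        val, chosen = mwis_intervals(items)
        # brute force over all subsets
        best = 0
        for size in range(1, len(items) + 1):
            for sub in itertools.combinations(items, size):
                ok = all(
                    a[1] < b[0] or b[1] < a[0]
                    for i, a in enumerate(sub)
                    for b in sub[i + 1:]
                )
                if ok:
                    best = max(best, sum(w for _, _, w in sub))
        assert val == best
        # chosen set is disjoint and attains the value
        assert all(
            a[1] < b[0] for a, b in zip(chosen, chosen[1:])
        )


def test_il_nc_median_toy():
    median, mcost = il_nc_median(TOY)
    assert median.to_dotbracket() == "((...))"
    assert mcost == 3


def test_il_nc_median_two_trees():
    _, mcost = il_nc_median([t("((...))"), t("(.....)")])
    assert mcost == 3


def test_rf_ilc_median_toy():
    median, mcost = rf_ilc_median(TOY)
    assert {(1, 7), (2, 6)} <= median.internal_nodes
    assert mcost <= 1


def test_rf_ilc_median_two_trees():
    _, mcost = rf_ilc_median([t("((...))"), t("(.....)")])
    assert mcost == 1


def test_median_cost():
    assert median_cost(t("((...))"), TOY, "rf") == 1
    assert median_cost(t("((...))"), TOY, "il") == 3
    assert median_cost(t("((...))"), [t("((...))")] * 3, "re") == 0


@pytest.mark.parametrize("n", [6, 7, 8])
def test_rf_median_optimal_brute_force(n, make_trees):
    candidates = all_trees(n, 0)
    for seed in range(12):
        p = 2 + seed % 3
        trees = make_trees(p, n, 0, seed)
        median, mcost = rf_median(trees)
        best, _ = brute_force_median(trees, rf_distance, candidates)
        assert mcost == best
        # conflict-free by construction: reassembling the DL set succeeds
        assert tree_from_dls(median.internal_nodes, n) == median


@pytest.mark.parametrize("n", [6, 7, 8])
def test_il_nc_median_optimal_brute_force(n, make_trees):
    candidates = all_trees(n, 0)
    for seed in range(12):
        p = 2 + seed % 3
        trees = make_trees(p, n, 0, seed + 100)
        _, mcost = il_nc_median(trees)
        best, _ = brute_force_median(trees, il_distance, candidates)
        assert mcost == best


@pytest.mark.parametrize("n", [6, 7, 8])
def test_il_ilc_median_optimal_brute_force(n, make_trees):
    for seed in range(12):
        p = 2 + seed % 3
        trees = make_trees(p, n, 0, seed + 200)
        blocks = set().union(*(internal_leafsets(tr) for tr in trees))
        median, mcost = il_ilc_median(trees)
        best, _ = brute_force_partition_median(
            n, blocks, lambda b: il_cost(b, trees)
        )
        got = sum(il_cost(I, trees) for I in internal_leafsets(median))
        assert got == best
        # ILC constraint holds
        assert internal_leafsets(median) <= frozenset(blocks)
        # Mcost consistent with the constant-shift identity
        shift = sum(len(internal_leafsets(tr)) for tr in trees)
        assert mcost == best + shift


@pytest.mark.parametrize("n", [6, 7, 8])
def test_rf_ilc_median_optimal_brute_force(n, make_trees):
    for seed in range(12):
        p = 2 + seed % 3
        trees = make_trees(p, n, 0, seed + 300)
        blocks = set().union(*(internal_leafsets(tr) for tr in trees))

        def rf_block_cost(b):
            bp = (min(b), max(b))
            return len(trees) - 2 * sum(bp in tr.internal_nodes for tr in trees)

        median, mcost = rf_ilc_median(trees)
        best, optima = brute_force_partition_median(n, blocks, rf_block_cost)
        assert mcost == min(
            median_cost(M, trees, "rf") for M in optima
        )
        assert internal_leafsets(median) <= frozenset(blocks)


def test_constraint_containment(make_trees):
    """Unconstrained optima are never worse than constrained ones."""
    for seed in range(10):
        trees = make_trees(3, 8, 0, seed + 400)
        assert il_nc_median(trees)[1] <= il_ilc_median(trees)[1]
        assert rf_median(trees)[1] <= rf_ilc_median(trees)[1]


def test_duplication_monotonicity(make_trees):
    trees = make_trees(3, 8, 0, 500)
    for solver in (rf_median, il_ilc_median, il_nc_median):
        m1, c1 = solver(trees)
        m2, c2 = solver(trees + trees)
        assert c2 == 2 * c1
        assert m2 == m1


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        rf_median([])
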