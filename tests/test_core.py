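"""The RNA tree data model: parsing, conversions, leafsets, conflicts."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnatrees.core import (
    ParseError,
    RnaStructure,
    RnaTree,
    RnaTreeError,
    descendant_leafsets,
    dl_conflict,
    gaps,
    il_conflict,
    internal_leafsets,
    parse_dotbracket,
    structure_to_tree,
    to_dotbracket,
    tree_from_dls,
    tree_from_structural_partition,
    tree_to_structure,
)
from rnatrees.simulate import sample_uniform_structure

from oracles import all_structures_filter


@pytest.mark.parametrize(
    "s,expected",
    [
        ("((...))", {(1, 7), (2, 6)}),
        (".......", set()),
        ("(.(.).)", {(1, 7), (3, 5)}),
        ("(...)..", {(1, 5)}),
    ],
)
def test_parse_dotbracket(s, expected):
    R = parse_dotbracket(s)
    assert R.n == len(s)
    assert R.pairs == frozenset(expected)
    assert to_dotbracket(R) == s


@pytest.mark.parametrize("bad", ["((...)", "...)..", "(x)", ""])
def test_parse_errors(bad):
    with pytest.raises(ParseError):
        parse_dotbracket(bad)


def test_parse_error_names_position():
    with pytest.raises(ParseError, match="position 5"):
        parse_dotbracket("....)..")


def test_structure_invariants():
    with pytest.raises(RnaTreeError):  # crossing
        RnaStructure(n=6, pairs={(1, 4), (2, 6)})
    with pytest.raises(RnaTreeError):  # shared endpoint
        RnaStructure(n=6, pairs={(1, 4), (4, 6)})
    with pytest.raises(RnaTreeError):  # non-canonical pairing
        RnaStructure(n=5, pairs={(1, 5)}, sequence="AAAAA")
    # Wobble is accepted
    RnaStructure(n=5, pairs={(1, 5)}, sequence="GAAAU")


def test_structure_to_tree_examples():
    T = structure_to_tree(parse_dotbracket("((...))"))
    assert T.internal_nodes == {(0, 8), (1, 7), (2, 6)}
    assert T.internal_leafset((2, 6)) == frozenset({2, 3, 4, 5, 6})

    flat = structure_to_tree(RnaStructure(n=3))
    assert flat.internal_nodes == {(0, 4)}
    assert flat.internal_leafset((0, 4)) == frozenset(range(5))

    T2 = structure_to_tree(RnaStructure(n=9, pairs={(1, 5), (6, 9)}))
    # root children: internal nodes ordered left to right
    assert T2.children((0, 10)) == [(1, 5), (6, 9)]


def test_descendant_and_internal_leafsets():
    T = structure_to_tree(parse_dotbracket("((...))"))
    assert descendant_leafsets(T) == frozenset({(0, 8), (1, 7), (2, 6)})
    assert internal_leafsets(T) == frozenset(
        {frozenset({0, 8}), frozenset({1, 7}), frozenset(range(2, 7))}
    )
    T3 = structure_to_tree(parse_dotbracket("(.(.).)"))
    assert internal_leafsets(T3) == frozenset(
        {frozenset({0, 8}), frozenset({1, 2, 6, 7}), frozenset({3, 4, 5})}
    )


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((1, 5), (3, 8), True),
        ((1, 5), (2, 4), False),
        ((1, 5), (6, 9), False),
        ((1, 5), (1, 5), False),
    ],
)
def test_dl_conflict(x, y, expected):
    assert dl_conflict(x, y) is expected
    assert dl_conflict(y, x) is expected


@pytest.mark.parametrize(
    "I,J,expected",
    [
        ({1, 7}, {2, 6}, False),  # J inside one gap of I
        ({1, 4}, {2, 6}, True),  # interleaving
        ({1, 4}, {4, 6}, True),  # intersection
        ({1, 4, 9}, {5, 7}, False),  # inside the gap [5, 8]
        ({1, 4, 9}, {5, 7, 10}, True),  # straddles element 9
        ({0, 8}, {1, 7}, False),
    ],
)
def test_il_conflict(I, J, expected):
    assert il_conflict(frozenset(I), frozenset(J)) is expected
    assert il_conflict(frozenset(J), frozenset(I)) is expected


def test_gaps():
    assert gaps({1, 7}) == [(2, 6)]
    assert gaps({1, 2, 6, 7}) == [(3, 5)]
    assert gaps({0, 3, 8}) == [(1, 2), (4, 7)]
    assert gaps({3, 4}) == []


def test_tree_from_dls():
    T = tree_from_dls({(0, 8), (1, 7), (2, 6)}, 7)
    assert T.to_dotbracket() == "((...))"
    assert tree_from_dls({(0, 8)}, 7).to_dotbracket() == "......."
    with pytest.raises(RnaTreeError):
        tree_from_dls({(0, 8), (1, 5), (3, 8)}, 7)  # conflicting
    with pytest.raises(RnaTreeError):
        tree_from_dls({(1, 7)}, 7)  # missing full interval


def test_tree_from_structural_partition():
    blocks = [{0, 8}, {1, 7}, {2, 3, 4, 5, 6}]
    assert tree_from_structural_partition(map(frozenset, blocks)).to_dotbracket() == "((...))"
    flat = [{0, 8}, {1, 2, 3, 4, 5, 6, 7}]
    assert tree_from_structural_partition(map(frozenset, flat)).to_dotbracket() == "(.....)"
    with pytest.raises(RnaTreeError):  # positions uncovered
        tree_from_structural_partition([frozenset({0, 8}), frozenset({1, 7})])
    with pytest.raises(RnaTreeError):  # singleton block
        tree_from_structural_partition(
            [frozenset({0, 8}), frozenset({1}), frozenset(range(2, 8))]
        )
    with pytest.raises(RnaTreeError):  # 0 and n+1 apart
        tree_from_structural_partition([frozenset({0, 1}), frozenset(range(2, 9))])


def test_roundtrips_exhaustive_small():
    """structure <-> tree <-> DL/IL collections all invert, for every
    structure up to length 8."""
    for n in range(1, 9):
        for s in all_structures_filter(n, 0):
            R = parse_dotbracket(s)
            T = structure_to_tree(R)
            assert tree_to_structure(T) == R
            assert tree_from_dls(descendant_leafsets(T), n) == T
            assert tree_from_structural_partition(internal_leafsets(T)) == T
            # DL collection is conflict-free
            dls = sorted(descendant_leafsets(T))
            assert not any(
                dl_conflict(a, b) for a in dls for b in dls if a != b
            )
            # IL collection partitions [0, n+1]; endpoints match nodes
            ils = internal_leafsets(T)
            assert sorted(x for I in ils for x in I) == list(range(n + 2))
            for node in T.internal_nodes:
                il = T.internal_leafset(node)
                assert (min(il), max(il)) == node


@settings(max_examples=50, derandomize=True)
@given(st.integers(10, 100), st.integers(0, 2**30))
def test_roundtrip_random(n, seed):
    R = sample_uniform_structure(n, 3, random.Random(seed))
    assert parse_dotbracket(to_dotbracket(R)) == R
    T = structure_to_tree(R)
    assert tree_to_structure(T) == R
    assert tree_from_dls(descendant_leafsets(T), n) == T
    assert tree_from_structural_partition(internal_leafsets(T)) == T


def test_rna_tree_rejects_bad_nodes():
    with pytest.raises(RnaTreeError):
        RnaTree(n=7, internal_nodes=frozenset({(1, 7)}))  # missing root
    with pytest.raises(RnaTreeError):
        RnaTree(n=7, internal_nodes=frozenset({(0, 8), (0, 5)}))  # fictive reuse
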