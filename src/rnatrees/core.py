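"""RNA tree data model.

An RNA secondary structure of length ``n`` is a set of non-crossing base
pairs over positions ``1..n``.  Its tree representation is an ordered rooted
tree whose leaves are the positions ``0..n+1`` (two fictive flanking
positions included) and whose internal nodes are the base pairs, plus a
fictive root pair ``(0, n+1)``.  The leftmost and rightmost child of an
internal node ``(i, j)`` are the leaves ``i`` and ``j`` themselves; the
remaining leaf-children are the unpaired positions directly inside the loop
closed by ``(i, j)``.

Two interval families drive all algorithms in this package:

* the *descendant leafset* (DL) of a node ``(i, j)`` is the interval
  ``[i, j]`` — the tree analogue of a clade;
* the *internal leafset* (IL) of a node is the set of its leaf-children —
  the loop closed by the pair.

This module provides dot-bracket parsing, structure/tree conversion in both
directions, DL/IL extraction, the two conflict predicates, and the inverse
constructions (tree from a conflict-free DL collection, tree from a
structural partition of the leafset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

__all__ = [
    "RnaTreeError",
    "ParseError",
    "RnaStructure",
    "RnaTree",
    "parse_dotbracket",
    "to_dotbracket",
    "structure_to_tree",
    "tree_to_structure",
    "descendant_leafsets",
    "internal_leafsets",
    "dl_conflict",
    "il_conflict",
    "gaps",
    "tree_from_dls",
    "tree_from_structural_partition",
]

#: Watson-Crick plus Wobble pairs — the only chemically valid pairings.
CANONICAL_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}


class RnaTreeError(ValueError):
    """Invalid structure, tree, or collection thereof."""


class ParseError(RnaTreeError):
    """Malformed dot-bracket input."""


def _check_nested_or_disjoint(pairs, *, strict: bool, what: str) -> None:
    """Raise unless every two intervals are nested or disjoint.

    With ``strict=True`` sharing an endpoint is also rejected (base pairs
    occupy their endpoints exclusively).
    """
    events = sorted(pairs)
    stack: list[tuple[int, int]] = []
    for (i, j) in events:
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack:
            k, l = stack[-1]
            inside = (k < i and j < l) if strict else (k <= i and j <= l)
            if not inside:
                raise RnaTreeError(
                    f"{what} ({i},{j}) and ({k},{l}) are neither nested nor disjoint"
                )
            if strict and (i == k or i == l or j == k or j == l):
                raise RnaTreeError(f"{what} ({i},{j}) shares a position with ({k},{l})")
        stack.append((i, j))
    seen_left = {}
    if strict:
        positions: set[int] = set()
        for (i, j) in events:
            if i in positions or j in positions:
                raise RnaTreeError(f"{what} endpoint reused in ({i},{j})")
            positions.add(i)
            positions.add(j)
    del seen_left


@dataclass(frozen=True)
class RnaStructure:
    """A secondary structure: length ``n``, non-crossing pairs, optional sequence.

    Pairs use 1-based sequence coordinates ``1 <= i < j <= n``.  When a
    sequence is given, every pair must be Watson-Crick or Wobble.
    """

    n: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.n < 1:
            raise RnaTreeError(f"length must be positive, got {self.n}")
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        for (i, j) in self.pairs:
            if not (1 <= i < j <= self.n):
                raise RnaTreeError(f"pair ({i},{j}) out of range for n={self.n}")
        _check_nested_or_disjoint(self.pairs, strict=True, what="pairs")
        if self.sequence is not None:
            if len(self.sequence) != self.n:
                raise RnaTreeError(
                    f"sequence length {len(self.sequence)} != n={self.n}"
                )
            bad = set(self.sequence) - set("ACGU")
            if bad:
                raise RnaTreeError(f"sequence contains non-ACGU symbols {sorted(bad)}")
            for (i, j) in self.pairs:
                duo = self.sequence[i - 1] + self.sequence[j - 1]
                if duo not in CANONICAL_PAIRS:
                    raise RnaTreeError(
                        f"pair ({i},{j}) is {duo}: not Watson-Crick or Wobble"
                    )

    def to_dotbracket(self) -> str:
        return to_dotbracket(self)


@dataclass(frozen=True)
class RnaTree:
    """Ordered rooted tree over leafset ``[0, n+1]``.

    Internal nodes are the pairs ``(i, j)`` (base pairs plus the fictive
    root ``(0, n+1)``), pairwise strictly nested or disjoint.  Children
    order is derived from leaf positions, never stored.
    """

    n: int
    internal_nodes: frozenset[tuple[int, int]]

    def __post_init__(self):
        object.__setattr__(
            self, "internal_nodes", frozenset(tuple(p) for p in self.internal_nodes)
        )
        root = (0, self.n + 1)
        if root not in self.internal_nodes:
            raise RnaTreeError(f"missing root node {root}")
        for (i, j) in self.internal_nodes:
            if not (0 <= i < j <= self.n + 1):
                raise RnaTreeError(f"node ({i},{j}) out of range for n={self.n}")
            if (i, j) != root and not (1 <= i and j <= self.n):
                raise RnaTreeError(f"node ({i},{j}) uses fictive positions")
        _check_nested_or_disjoint(
            self.internal_nodes - {root}, strict=True, what="internal nodes"
        )

    @cached_property
    def _children(self) -> dict[tuple[int, int], list[tuple[int, int]]]:
        """Internal-node children of each internal node, left to right."""
        kids: dict[tuple[int, int], list[tuple[int, int]]] = {
            x: [] for x in self.internal_nodes
        }
        stack: list[tuple[int, int]] = []
        for node in sorted(self.internal_nodes, key=lambda p: (p[0], -p[1])):
            while stack and stack[-1][1] < node[1]:
                stack.pop()
            if stack:
                kids[stack[-1]].append(node)
            stack.append(node)
        return kids

    @cached_property
    def _internal_leafsets(self) -> frozenset[frozenset[int]]:
        return frozenset(self.internal_leafset(x) for x in self.internal_nodes)

    @property
    def root(self) -> tuple[int, int]:
        return (0, self.n + 1)

    def children(self, node: tuple[int, int]) -> list[tuple[int, int]]:
        """Internal-node children of ``node``, in left-to-right order."""
        return list(self._children[node])

    def internal_leafset(self, node: tuple[int, int]) -> frozenset[int]:
        """Leaf-children of ``node``: its endpoints plus uncovered inner positions."""
        i, j = node
        members = {i, j}
        pos = i + 1
        for (k, l) in self._children[node]:
            members.update(range(pos, k))
            pos = l + 1
        members.update(range(pos, j))
        return frozenset(members)

    def to_structure(self, sequence: Optional[str] = None) -> RnaStructure:
        return tree_to_structure(self, sequence)

    def to_dotbracket(self) -> str:
        return to_dotbracket(self.to_structure())

    @property
    def num_base_pairs(self) -> int:
        """Base pairs displayed (fictive root excluded)."""
        return len(self.internal_nodes) - 1


def parse_dotbracket(s: str, sequence: Optional[str] = None) -> RnaStructure:
    """Parse a dot-bracket string into an :class:`RnaStructure`.

    Raises :class:`ParseError` with a 1-based position on unbalanced input.
    """
    if not s:
        raise ParseError("empty dot-bracket string")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ParseError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}: unclosed at end of string")
    return RnaStructure(n=len(s), pairs=frozenset(pairs), sequence=sequence)


def to_dotbracket(R: RnaStructure) -> str:
    """Write ``R`` as a dot-bracket string (inverse of :func:`parse_dotbracket`)."""
    chars = ["."] * R.n
    for (i, j) in R.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def structure_to_tree(R: RnaStructure) -> RnaTree:
    """Tree representation: pairs plus the fictive root ``(0, n+1)``."""
    return RnaTree(n=R.n, internal_nodes=frozenset(R.pairs) | {(0, R.n + 1)})


def tree_to_structure(T: RnaTree, sequence: Optional[str] = None) -> RnaStructure:
    """Inverse of :func:`structure_to_tree`: strip the fictive root."""
    return RnaStructure(
        n=T.n, pairs=T.internal_nodes - {T.root}, sequence=sequence
    )


def descendant_leafsets(T: RnaTree) -> frozenset[tuple[int, int]]:
    """DL collection of ``T``: node ``(i, j)`` contributes the interval ``[i, j]``.

    Under this representation the DL of a node *is* the node, so the
    collection coincides with the internal-node set.
    """
    return T.internal_nodes


def internal_leafsets(T: RnaTree) -> frozenset[frozenset[int]]:
    """IL collection of ``T``: one leaf-children set per internal node."""
    return T._internal_leafsets


def dl_conflict(X: tuple[int, int], Y: tuple[int, int]) -> bool:
    """True iff intervals ``X`` and ``Y`` overlap without containment."""
    a, b = X
    c, d = Y
    if b < c or d < a:
        return False
    return not (a <= c and d <= b) and not (c <= a and b <= d)


def il_conflict(I: frozenset[int], J: frozenset[int]) -> bool:
    """True iff the two ILs intersect or interleave.

    ``I`` and ``J`` interleave when there exist ``i, j in I`` and
    ``k, l in J`` with ``i < k < j < l`` or ``k < i < l < j``.
    """
    I, J = frozenset(I), frozenset(J)
    if I & J:
        return True
    a, b = min(I), max(I)
    c, d = min(J), max(J)
    if b < c or d < a:
        return False
    if a < c and b < d:  # spans partially overlap: a < c <= b < d
        return True
    if c < a and d < b:
        return True
    # one span inside the other: conflict iff an outer element falls strictly
    # inside the inner span (the inner IL must then sit across a gap boundary)
    if a < c and d < b:
        return any(c < x < d for x in I)
    return any(a < x < b for x in J)


def gaps(I: Iterable[int]) -> list[tuple[int, int]]:
    """Maximal intervals between consecutive members of ``I``.

    Each gap ``[x, y]`` satisfies ``x-1 in I`` and ``y+1 in I`` with no
    member of ``I`` inside.
    """
    members = sorted(set(I))
    if len(members) < 2:
        raise RnaTreeError("an internal leafset has at least 2 members")
    out = []
    for a, b in zip(members, members[1:]):
        if b - a > 1:
            out.append((a + 1, b - 1))
    return out


def tree_from_dls(dls: Iterable[tuple[int, int]], n: int) -> RnaTree:
    """Unique tree whose DL collection equals ``dls``.

    ``dls`` must be pairwise non-conflicting and contain ``[0, n+1]``.
    """
    nodes = frozenset(tuple(d) for d in dls)
    if (0, n + 1) not in nodes:
        raise RnaTreeError(f"DL collection must contain the full interval (0,{n + 1})")
    try:
        return RnaTree(n=n, internal_nodes=nodes)
    except RnaTreeError as exc:
        raise RnaTreeError(f"invalid DL collection: {exc}") from exc


def tree_from_structural_partition(blocks: Iterable[frozenset[int]]) -> RnaTree:
    """Unique tree whose IL collection equals ``blocks``.

    ``blocks`` must be a structural partition of ``[0, n+1]`` — pairwise
    non-conflicting sets of size >= 2 that partition the leafset — with 0
    and ``n+1`` in the same block.
    """
    blocks = [frozenset(b) for b in blocks]
    if not blocks:
        raise RnaTreeError("empty partition")
    all_members: list[int] = []
    for b in blocks:
        if len(b) < 2:
            raise RnaTreeError(f"block {sorted(b)} has size < 2")
        all_members.extend(b)
    lo, hi = min(all_members), max(all_members)
    if lo != 0:
        raise RnaTreeError("partition must start at leaf 0")
    if len(all_members) != len(set(all_members)):
        raise RnaTreeError("blocks are not disjoint")
    if set(all_members) != set(range(lo, hi + 1)):
        raise RnaTreeError(f"blocks do not cover [{lo},{hi}]")
    root_block = next(b for b in blocks if 0 in b)
    if hi not in root_block:
        raise RnaTreeError(f"leaves 0 and {hi} are in different blocks")
    for idx, b in enumerate(blocks):
        for b2 in blocks[idx + 1:]:
            if il_conflict(b, b2):
                raise RnaTreeError(
                    f"blocks {sorted(b)} and {sorted(b2)} conflict"
                )
    n = hi - 1
    nodes = frozenset((min(b), max(b)) for b in blocks)
    T = RnaTree(n=n, internal_nodes=nodes)
    if internal_leafsets(T) != frozenset(blocks):
        raise RnaTreeError("blocks do not form the IL collection of any RNA tree")
    return T
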