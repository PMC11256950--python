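"""Uniform sampling of secondary structures and random phylogeny instances.

A structure of length ``m`` with minimum hairpin size ``theta`` is a
well-parenthesized dot-bracket string in which every pair ``(i, j)``
encloses at least ``theta`` positions (``j - i - 1 >= theta``).  The count
``S[m]`` follows the first-position decomposition

    S[m] = S[m-1] + sum_{j = theta+2}^{m} S[j-2] * S[m-j]

(position 1 unpaired, or paired to some admissible ``j``), with ``S[m] = 1``
for ``0 <= m <= theta+1``.  Exact uniform sampling is a stochastic backtrack
over the same decomposition, so every admissible structure has probability
exactly ``1 / S[m]`` — the zero-temperature limit of Boltzmann sampling.

The benchmark instances are complete binary phylogenies of height ``H``
whose leaves carry independent uniform structures; defaults ``H=5``,
``m=100``, ``theta=3``.
"""

from __future__ import annotations

import random
from functools import lru_cache
from typing import Iterator, Union

from .core import RnaStructure
from .parsimony import PhyloNode, Phylogeny

__all__ = [
    "count_structures",
    "sample_uniform_structure",
    "enumerate_structures",
    "complete_binary_phylogeny",
    "random_instance",
]

Rng = Union[int, random.Random]


def _rng(seed_or_rng: Rng) -> random.Random:
    if isinstance(seed_or_rng, random.Random):
        return seed_or_rng
    return random.Random(seed_or_rng)


@lru_cache(maxsize=None)
def _count_table(m: int, theta: int) -> tuple[int, ...]:
    S = [1] * (min(m, theta + 1) + 1)
    for length in range(theta + 2, m + 1):
        total = S[length - 1]
        for j in range(theta + 2, length + 1):
            total += S[j - 2] * S[length - j]
        S.append(total)
    return tuple(S)


def count_structures(m: int, theta: int = 3) -> int:
    """Exact number of structures of length ``m`` with hairpin size >= ``theta``.

    Arbitrary precision; ``theta=0`` gives the Motzkin numbers.
    """
    if m < 0:
        raise ValueError("length must be non-negative")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return _count_table(m, theta)[m]


def sample_uniform_structure(m: int, theta: int = 3, rng: Rng = 0) -> RnaStructure:
    """Draw one structure uniformly among all admissible ones of length ``m``.

    Deterministic for a given seed or :class:`random.Random` state.
    """
    if m < 1:
        raise ValueError("length must be positive")
    r = _rng(rng)
    S = _count_table(m, theta)
    pairs: set[tuple[int, int]] = set()

    def backtrack(lo: int, length: int) -> None:
        # sample the structure of positions lo .. lo+length-1
        while length > theta + 1:
            ticket = r.randrange(S[length])
            if ticket < S[length - 1]:
                lo += 1
                length -= 1
                continue
            ticket -= S[length - 1]
            for j in range(theta + 2, length + 1):
                block = S[j - 2] * S[length - j]
                if ticket < block:
                    pairs.add((lo, lo + j - 1))
                    backtrack(lo + 1, j - 2)
                    lo += j
                    length -= j
                    break
                ticket -= block
            else:  # pragma: no cover - counts and decomposition agree
                raise AssertionError("sampling ticket out of range")

    backtrack(1, m)
    return RnaStructure(n=m, pairs=frozenset(pairs))


def enumerate_structures(m: int, theta: int = 3) -> Iterator[str]:
    """Yield every admissible dot-bracket string of length ``m``.

    Follows the counting decomposition, so the number of strings yielded is
    exactly :func:`count_structures`; intended for exhaustive verification
    at small ``m``.
    """
    if m == 0:
        yield ""
        return
    if m <= theta + 1:
        yield "." * m
        return
    for rest in enumerate_structures(m - 1, theta):
        yield "." + rest
    for j in range(theta + 2, m + 1):
        for inner in enumerate_structures(j - 2, theta):
            for rest in enumerate_structures(m - j, theta):
                yield "(" + inner + ")" + rest


def complete_binary_phylogeny(height: int) -> Phylogeny:
    """Complete binary phylogeny of the given height with 2**height leaves.

    Leaves are named ``L1 .. L{2**height}`` left to right.
    """
    if height < 1:
        raise ValueError("height must be >= 1")
    counter = iter(range(1, 2**height + 1))

    def build(depth: int) -> PhyloNode:
        if depth == height:
            return PhyloNode(name=f"L{next(counter)}")
        return PhyloNode(children=[build(depth + 1), build(depth + 1)])

    return Phylogeny(build(0))


def random_instance(
    height: int = 5, m: int = 100, theta: int = 3, rng: Rng = 0
) -> tuple[Phylogeny, dict[str, RnaStructure]]:
    """A complete binary phylogeny with i.i.d. uniform leaf structures.

    Defaults reproduce the benchmark conditions: height 5 (32 leaves),
    length 100, minimum hairpin size 3.
    """
    r = _rng(rng)
    phylo = complete_binary_phylogeny(height)
    structures = {
        leaf.name: sample_uniform_structure(m, theta, r) for leaf in phylo.leaves()
    }
    return phylo, structures
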