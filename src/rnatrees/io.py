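"""Readers and writers: dot-bracket sets, Stockholm alignments, Newick.

Also implements the alignment preprocessing that turns a gapped seed
alignment with a consensus structure into a set of gap-free, equal-length
per-sequence structures:

1. :func:`per_sequence_structure` keeps a consensus pair for a sequence only
   if the two nucleotides form a Watson-Crick or Wobble pair and neither
   position is gapped;
2. :func:`project_gapless` deletes every alignment column containing a gap
   in any sequence and renumbers the surviving positions; a pair losing one
   endpoint leaves its partner unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO, Union

import dendropy

from .core import (
    CANONICAL_PAIRS,
    ParseError,
    RnaStructure,
    RnaTreeError,
    parse_dotbracket,
    to_dotbracket,
)
from .parsimony import PhyloNode, Phylogeny, SpAssignment

__all__ = [
    "AlignedFamily",
    "read_dotbracket",
    "write_dotbracket",
    "per_sequence_structure",
    "project_gapless",
    "read_stockholm",
    "read_newick",
    "write_newick",
]

#: gap symbols accepted in Stockholm sequence rows
GAP_CHARS = set("-._~")

#: WUSS bracket families normalized to plain parentheses
_WUSS_OPEN = set("<([{")
_WUSS_CLOSE = set(">)]}")


@dataclass
class AlignedFamily:
    """A family alignment: equal-length rows plus structure annotations.

    ``structures`` holds per-sequence pair sets in alignment coordinates
    (1-based columns); ``consensus`` is the consensus structure string over
    the same columns, when available.
    """

    ids: list[str]
    rows: list[str]
    structures: list[frozenset[tuple[int, int]]] = field(default_factory=list)
    consensus: Optional[str] = None

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths {sorted(lengths)}")
        if self.consensus is not None and self.rows and len(self.consensus) != len(self.rows[0]):
            raise ValueError("consensus length differs from alignment length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_dotbracket(source: Union[str, Path, TextIO]) -> list[tuple[str, RnaStructure]]:
    """Read structures from plain-line or FASTA-style dot-bracket text.

    Plain format: one structure per line, auto-named ``S1, S2, ...``.
    FASTA-style: ``>id`` header lines followed by one structure line each.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("no structures found")
    out: list[tuple[str, RnaStructure]] = []
    if lines[0].startswith(">"):
        name = None
        for ln in lines:
            if ln.startswith(">"):
                name = ln[1:].split()[0]
            else:
                if name is None:
                    raise ParseError("structure line before any '>' header")
                out.append((name, parse_dotbracket(ln)))
                name = None
    else:
        for k, ln in enumerate(lines, start=1):
            out.append((f"S{k}", parse_dotbracket(ln)))
    return out


def write_dotbracket(
    records: Sequence[tuple[str, RnaStructure]], path: Union[str, Path, None] = None
) -> str:
    """Write FASTA-style dot-bracket records; returns the text."""
    text = "".join(f">{name}\n{to_dotbracket(R)}\n" for name, R in records)
    if path is not None:
        Path(path).write_text(text)
    return text


def _is_valid_pairing(a: str, b: str) -> bool:
    duo = (a + b).upper().replace("T", "U")
    return duo in CANONICAL_PAIRS


def per_sequence_structure(consensus: str, sequence: str) -> frozenset[tuple[int, int]]:
    """Project a consensus structure onto one aligned sequence.

    Keeps a consensus pair only if the sequence's two characters form a
    Watson-Crick or Wobble pair; pairs touching a gap character are dropped.
    Returns the kept pairs in alignment coordinates.
    """
    if len(consensus) != len(sequence):
        raise ValueError(
            f"consensus length {len(consensus)} != sequence length {len(sequence)}"
        )
    pairs = _parse_consensus(consensus)
    kept = set()
    for (i, j) in pairs:
        a, b = sequence[i - 1], sequence[j - 1]
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        if _is_valid_pairing(a, b):
            kept.add((i, j))
    return frozenset(kept)


def _parse_consensus(consensus: str) -> frozenset[tuple[int, int]]:
    """Pairs of a consensus line: dot-bracket or WUSS.

    All four WUSS bracket families are treated as one nested family;
    pseudoknot letters and other annotation symbols count as unpaired.
    Crossing brackets after this normalization are an error.
    """
    normalized = []
    for ch in consensus:
        if ch in _WUSS_OPEN:
            normalized.append("(")
        elif ch in _WUSS_CLOSE:
            normalized.append(")")
        else:
            normalized.append(".")
    try:
        return parse_dotbracket("".join(normalized)).pairs
    except (ParseError, RnaTreeError) as exc:
        raise ParseError(f"invalid consensus structure: {exc}") from exc


def project_gapless(family: AlignedFamily) -> list[RnaStructure]:
    """Delete every column gapped in any row; renumber surviving positions.

    A pair with exactly one surviving endpoint becomes unpaired.  All output
    structures share the new (common) length.
    """
    if not family.structures or len(family.structures) != len(family.rows):
        raise ValueError("per-sequence structures must be computed first")
    ncols = family.ncols
    keep = [
        col
        for col in range(1, ncols + 1)
        if all(row[col - 1] not in GAP_CHARS for row in family.rows)
    ]
    if not keep:
        raise ValueError("projection is empty: every column contains a gap")
    new_pos = {col: idx + 1 for idx, col in enumerate(keep)}
    out = []
    for pairs in family.structures:
        projected = {
            (new_pos[i], new_pos[j])
            for (i, j) in pairs
            if i in new_pos and j in new_pos
        }
        out.append(RnaStructure(n=len(keep), pairs=frozenset(projected)))
    return out


def read_stockholm(source: Union[str, Path, TextIO]) -> AlignedFamily:
    """Read a Stockholm 1.0 alignment with a consensus-structure line.

    Uses Biopython's Stockholm parser; the ``#=GC SS_cons`` column
    annotation is required.  Per-sequence structures are computed by
    projecting the consensus onto each row.
    """
    from Bio import AlignIO

    if hasattr(source, "read"):
        aln = AlignIO.read(source, "stockholm")
    else:
        with open(source) as fh:
            aln = AlignIO.read(fh, "stockholm")
    consensus = aln.column_annotations.get("secondary_structure")
    if consensus is None:
        raise ParseError("Stockholm file has no consensus structure (#=GC SS_cons)")
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq) for rec in aln]
    structures = [per_sequence_structure(consensus, row) for row in rows]
    return AlignedFamily(ids=ids, rows=rows, structures=structures, consensus=consensus)


def _from_dendropy(node: "dendropy.Node") -> PhyloNode:
    label = None
    if node.taxon is not None:
        label = node.taxon.label
    elif node.label:
        label = node.label
    out = PhyloNode(name=label, edge_length=node.edge.length)
    out.children = [_from_dendropy(c) for c in node.child_nodes()]
    return out


def read_newick(source: Union[str, Path, TextIO]) -> Phylogeny:
    """Read a rooted, possibly multifurcating phylogeny from Newick.

    Branch lengths are retained but unused; duplicate leaf names are an
    error.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    from dendropy.utility.error import DataParseError

    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except DataParseError as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return Phylogeny(_from_dendropy(tree.seed_node))


def write_newick(
    phylo: Phylogeny,
    assignment: Optional[Mapping[PhyloNode, object]] = None,
    path: Union[str, Path, None] = None,
) -> str:
    """Write the phylogeny as Newick, naming internal nodes ``N1, N2, ...``.

    When an assignment is given, the generated internal names match the keys
    of :func:`assignment_table`, so the tree and the table cross-reference.
    """
    names = internal_names(phylo)

    def render(v: PhyloNode) -> str:
        if v.is_leaf:
            return v.name
        inner = ",".join(render(c) for c in v.children)
        return f"({inner}){names[v]}"

    text = render(phylo.root) + ";\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def internal_names(phylo: Phylogeny) -> dict[PhyloNode, str]:
    """Stable generated names for internal nodes, in postorder."""
    return {
        v: (v.name or f"N{k}")
        for k, v in enumerate(phylo.internal_nodes(), start=1)
    }


def assignment_table(phylo: Phylogeny, assignment: SpAssignment) -> list[tuple[str, str]]:
    """(node name, dot-bracket) rows for an internal-node assignment."""
    names = internal_names(phylo)
    return [
        (names[v], assignment.trees[v].to_dotbracket())
        for v in phylo.internal_nodes()
    ]
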