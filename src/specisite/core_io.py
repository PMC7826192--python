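"""Readers/writers for the formats the pipeline touches, and the mapping
between alignment columns and reference-sequence residue numbering.

All downstream position analyses are reported in the numbering of a
designated *reference* sequence (e.g. human SIRT1 in UniProt numbering),
so the central object here is :class:`MultipleAlignment`, which carries a
``column_map`` from alignment columns to reference residue numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
ALPHABET = set(AMINO_ACIDS) | {GAP}

_START_RE = re.compile(r"\bstart=(\d+)\b")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class AlignedSequence:
    """One row of a protein multiple sequence alignment.

    Parameters
    ----------
    id : str
        Sequence identifier (must match a tree tip when used with a tree).
    residues : str
        Aligned residues over the 20 amino acids plus ``'-'``.
    clade : str
        Free-form clade label; sequences without an assignment carry
        ``"unassigned"``.
    """

    id: str
    residues: str
    clade: str = "unassigned"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """A validated alignment with a reference-numbering column map.

    ``column_map[col]`` gives the reference residue number (1-based in the
    reference's own numbering convention) at alignment column ``col``
    (0-based); columns where the reference is gapped are absent from the
    map.
    """

    sequences: list[AlignedSequence]
    reference_id: str
    column_map: dict[int, int] = field(default_factory=dict)
    numbering_start: int = 1

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("alignment is empty")
        L = len(self.sequences[0])
        for s in self.sequences:
            if len(s) != L:
                raise FormatError(
                    f"ragged alignment: sequence {s.id!r} has length "
                    f"{len(s)}, expected {L}"
                )
        ids = {s.id for s in self.sequences}
        if self.reference_id not in ids:
            raise KeyError(f"reference {self.reference_id!r} not in alignment")
        if not self.column_map:
            self.column_map = _build_column_map(
                self.reference_sequence(), self.numbering_start
            )
        nums = list(self.column_map.values())
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise FormatError("reference residue numbers not strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def reference_sequence(self) -> AlignedSequence:
        return next(s for s in self.sequences if s.id == self.reference_id)

    def column_for_residue(self, residue_number: int) -> int:
        """Inverse of ``column_map``; raises ``KeyError`` for unmapped numbers."""
        for col, num in self.column_map.items():
            if num == residue_number:
                return col
        raise KeyError(f"residue number {residue_number} not mapped")

    def column(self, col: int) -> str:
        """Residue characters of alignment column ``col``, one per sequence."""
        return "".join(s.residues[col] for s in self.sequences)

    def mapped_residue_numbers(self) -> list[int]:
        return list(self.column_map.values())

    def to_matrix(self) -> np.ndarray:
        """Integer-coded alignment, shape (n_seq, n_col); gap encoded as 20."""
        code = np.full((len(self.sequences), self.n_columns), 20, dtype=np.int8)
        for i, s in enumerate(self.sequences):
            code[i] = [AA_INDEX.get(c, 20) for c in s.residues]
        return code

    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.sequences:
            out.setdefault(s.clade, []).append(s.id)
        return out


@dataclass
class ResidueAnnotation:
    """Structural annotation of one reference residue.

    ``rsa`` is relative solvent accessibility in [0, 1]; ``coord`` is a
    representative-atom coordinate in Angstroms (convention: C-beta,
    C-alpha for glycine).
    """

    residue_number: int
    rsa: Optional[float] = None
    coord: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.rsa is not None and not (0.0 <= self.rsa <= 1.0):
            raise ValueError(
                f"rsa {self.rsa} for residue {self.residue_number} outside [0, 1]"
            )
        if self.coord is not None:
            self.coord = np.asarray(self.coord, dtype=float)
            if self.coord.shape != (3,):
                raise ValueError("coord must be a 3-vector")


class PhyloTree:
    """A rooted phylogeny with branch lengths and named internal nodes.

    Thin wrapper around a :class:`dendropy.Tree`; guarantees non-negative
    branch lengths and deterministic internal-node names ("N1", "N2", ...
    assigned in post-order to unnamed nodes).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate_and_name()

    def _validate_and_name(self) -> None:
        counter = 0
        for node in self.tree.postorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError(f"negative branch length {node.edge.length}")
            if node.is_leaf():
                if node.taxon is None:
                    raise FormatError("unnamed tip in tree")
                node.label = node.taxon.label
            elif not node.label:
                counter += 1
                node.label = f"N{counter}"
        labels = [n.label for n in self.tree.postorder_node_iter()]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate node names in tree")

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def internal_names(self) -> list[str]:
        return [
            n.label for n in self.tree.postorder_internal_node_iter()
        ]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def node(self, name: str) -> dendropy.Node:
        for n in self.tree.postorder_node_iter():
            if n.label == name:
                return n
        raise KeyError(f"node {name!r} not in tree")

    def newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    def check_tips_match(self, alignment: MultipleAlignment) -> None:
        tips = set(self.tip_names)
        ids = set(alignment.ids)
        if tips != ids:
            missing = sorted(tips ^ ids)[:5]
            raise ValueError(
                f"tree tips and alignment ids differ (first mismatches: {missing})"
            )


def _clean_residues(raw: str, seq_id: str) -> str:
    out = raw.upper().replace(".", GAP)
    for pos, c in enumerate(out):
        if c not in ALPHABET:
            raise FormatError(
                f"illegal character {c!r} in sequence {seq_id!r} at position {pos + 1}"
            )
    return out


def _build_column_map(reference: AlignedSequence, start: int = 1) -> dict[int, int]:
    cmap: dict[int, int] = {}
    num = start
    for col, c in enumerate(reference.residues):
        if c != GAP:
            cmap[col] = num
            num += 1
    return cmap


def read_alignment(
    path: str | Path,
    reference_id: str,
    clade_table: Optional[str | Path] = None,
) -> MultipleAlignment:
    """Read an aligned FASTA file and build the reference column map.

    The reference header may carry ``start=N`` to begin residue numbering
    at N (for constructs that are fragments of a full-length protein).
    ``clade_table`` is a two-column TSV (sequence id, clade label);
    sequences not listed get clade ``"unassigned"``.
    """
    clade_of: dict[str, str] = {}
    if clade_table is not None:
        for line in Path(clade_table).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"clade table line lacks two columns: {line!r}")
            clade_of[parts[0]] = parts[1]
    sequences = []
    start = 1
    for rec in SeqIO.parse(str(path), "fasta"):
        sequences.append(
            AlignedSequence(
                id=rec.id,
                residues=_clean_residues(str(rec.seq), rec.id),
                clade=clade_of.get(rec.id, "unassigned"),
            )
        )
        if rec.id == reference_id:
            m = _START_RE.search(rec.description)
            if m:
                start = int(m.group(1))
    if not sequences:
        raise FormatError(f"no sequences in {path}")
    return MultipleAlignment(
        sequences=sequences, reference_id=reference_id, numbering_start=start
    )


def write_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in alignment.sequences:
            fh.write(f">{s.id}\n{s.residues}\n")


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree; unnamed internal nodes are auto-named
    ``N1, N2, ...`` in post-order."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    _normalize_internal_labels(tree)
    return PhyloTree(tree)


def _normalize_internal_labels(tree: dendropy.Tree) -> None:
    """Move internal-node taxa onto node labels so writing does not
    duplicate them."""
    for node in tree.postorder_internal_node_iter():
        if node.taxon is not None:
            if not node.label:
                node.label = node.taxon.label
            node.taxon = None


def tree_from_newick(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    _normalize_internal_labels(tree)
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_residue_annotations(
    rsa_path: Optional[str | Path] = None,
    coord_path: Optional[str | Path] = None,
) -> list[ResidueAnnotation]:
    """Read and merge per-residue RSA and coordinate tables.

    RSA table: TSV ``residue_number<TAB>rsa``.  Coordinate table: TSV
    ``residue_number<TAB>x<TAB>y<TAB>z`` (representative atom, Angstroms).
    At least one table must be supplied; records are merged on residue
    number.
    """
    if rsa_path is None and coord_path is None:
        raise ValueError("need at least one of rsa_path, coord_path")
    merged: dict[int, ResidueAnnotation] = {}

    def rows(p: str | Path) -> Iterable[list[str]]:
        for line in Path(p).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("residue"):
                continue
            yield line.split("\t")

    if rsa_path is not None:
        seen: set[int] = set()
        for parts in rows(rsa_path):
            num = int(parts[0])
            if num in seen:
                raise ValueError(f"duplicate residue number {num} in RSA table")
            seen.add(num)
            merged[num] = ResidueAnnotation(residue_number=num, rsa=float(parts[1]))
    if coord_path is not None:
        seen = set()
        for parts in rows(coord_path):
            num = int(parts[0])
            if num in seen:
                raise ValueError(f"duplicate residue number {num} in coordinate table")
            seen.add(num)
            coord = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            if num in merged:
                merged[num].coord = coord
            else:
                merged[num] = ResidueAnnotation(residue_number=num, coord=coord)
    return [merged[k] for k in sorted(merged)]
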