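"""Phylogenetic profiling of an enzyme's substrate repertoire.

For each (substrate, species) cell the best local alignment of the human
substrate against the species' proteome is scored, converted to bits via
the Karlin--Altschul transform, and normalized by alignment length to a
conservation value ``c`` (bits/column).  A substrate is called *present*
in a species when ``c`` clears a threshold and the alignment covers a
minimum fraction of the substrate (short spurious local hits have a high
bits-per-column but negligible coverage, so the coverage requirement is
what makes the call specific).  For present cells, each annotated
acetyl-lysine of the human substrate is traced through the alignment to
test whether the modified lysine is conserved (*fixed*) in the ortholog.

Ordered against a species tree, the resulting matrix dates when each
substrate entered the repertoire: universally conserved substrates fill
every row, late-gained ones only the clades below their gain branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from specisite.core_io import PhyloTree


@dataclass
class BitScoreParams:
    """Karlin--Altschul parameters and alignment scoring scheme.

    Defaults are the standard gapped BLOSUM62 values (gap open 11,
    extend 1): lambda = 0.267 nats per raw-score unit, K = 0.041.
    """

    lam: float = 0.267
    K: float = 0.041
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass
class SubstrateRecord:
    """A substrate protein with its annotated acetyl-lysine positions
    (1-based in the human sequence)."""

    name: str
    sequence: str
    acetyl_k: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pos in self.acetyl_k:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(f"{self.name}: acetyl-K {pos} out of range")
            if self.sequence[pos - 1] != "K":
                raise ValueError(
                    f"{self.name}: position {pos} is "
                    f"{self.sequence[pos - 1]!r}, not K"
                )


@dataclass
class ProfileCell:
    substrate: str
    species: str
    raw_score: float
    alignment_length: int
    conservation: float  # bits per alignment column
    coverage: float  # aligned fraction of the substrate
    present: bool
    k_conserved: Optional[dict[int, bool]] = None  # defined only when present
    best_hit: Optional[str] = None


def _aligner(params: BitScoreParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def local_align_score(
    query: str, target: str, params: Optional[BitScoreParams] = None
) -> tuple[float, int, dict[int, int]]:
    """Best Smith--Waterman local alignment under affine gap penalties.

    Returns ``(S, L, column_map)``: raw score, alignment length in
    columns (gap columns included), and a 1-based map from aligned query
    positions to target positions.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    params = params or BitScoreParams()
    aligner = _aligner(params)
    alignments = aligner.align(query, target)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0, 0, {}
    qblocks, tblocks = best.aligned
    colmap: dict[int, int] = {}
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        for dq in range(q1 - q0):
            colmap[q0 + dq + 1] = t0 + dq + 1
    # alignment length = matched columns + gap columns between blocks
    L = 0
    for k, ((q0, q1), (t0, t1)) in enumerate(zip(qblocks, tblocks)):
        L += q1 - q0
        if k > 0:
            L += (q0 - qblocks[k - 1][1]) + (t0 - tblocks[k - 1][1])
    return float(best.score), L, colmap


def to_bits(S: float, params: Optional[BitScoreParams] = None) -> float:
    """Karlin--Altschul bit score: ``(lambda*S - ln K) / ln 2``."""
    params = params or BitScoreParams()
    return (params.lam * S - math.log(params.K)) / math.log(2.0)


def profile_cell(
    substrate: SubstrateRecord,
    species: str,
    proteome: dict[str, str],
    params: Optional[BitScoreParams] = None,
    presence_threshold: float = 0.5,
    min_coverage: float = 0.5,
) -> ProfileCell:
    """Best-hit conservation of one substrate in one species' proteome."""
    params = params or BitScoreParams()
    if not proteome:
        warnings.warn(f"empty proteome for species {species!r}")
        return ProfileCell(
            substrate=substrate.name,
            species=species,
            raw_score=0.0,
            alignment_length=0,
            conservation=0.0,
            coverage=0.0,
            present=False,
        )
    best = None
    for seq_id, seq in proteome.items():
        S, L, colmap = local_align_score(substrate.sequence, seq, params)
        if best is None or S > best[0]:
            best = (S, L, colmap, seq_id, seq)
    S, L, colmap, hit_id, hit_seq = best
    c = to_bits(S, params) / L if L > 0 else 0.0
    coverage = len(colmap) / len(substrate.sequence)
    present = c >= presence_threshold and coverage >= min_coverage
    k_cons = None
    if present:
        k_cons = {}
        for pos in substrate.acetyl_k:
            tpos = colmap.get(pos)
            k_cons[pos] = tpos is not None and hit_seq[tpos - 1] == "K"
    return ProfileCell(
        substrate=substrate.name,
        species=species,
        raw_score=S,
        alignment_length=L,
        conservation=c,
        coverage=coverage,
        present=present,
        k_conserved=k_cons,
        best_hit=hit_id,
    )


def profile_matrix(
    substrates: Sequence[SubstrateRecord],
    proteomes: dict[str, dict[str, str]],
    params: Optional[BitScoreParams] = None,
    presence_threshold: float = 0.5,
    min_coverage: float = 0.5,
) -> list[ProfileCell]:
    """All (substrate, species) cells, best-hit semantics per proteome."""
    cells = []
    for species, proteome in proteomes.items():
        for sub in substrates:
            cells.append(
                profile_cell(
                    sub, species, proteome, params, presence_threshold, min_coverage
                )
            )
    return cells


def order_matrix(
    cells: Sequence[ProfileCell], tree: PhyloTree
) -> tuple[list[str], list[str]]:
    """Display order for the profile matrix.

    Species (rows) follow the ladderized tree's leaf order; species
    absent from the tree are appended last, alphabetically, with a
    warning.  Substrates (columns) sort by fraction-present descending
    (conserved substrates first), ties alphabetical.
    """
    species = sorted({c.species for c in cells})
    t = tree.clone()
    t.tree.ladderize()
    tip_order = [leaf.taxon.label for leaf in t.tree.leaf_node_iter()]
    in_tree = [s for s in tip_order if s in species]
    extra = sorted(s for s in species if s not in tip_order)
    if extra:
        warnings.warn(f"species not in tree, appended last: {extra}")
    row_order = in_tree + extra
    frac: dict[str, list[bool]] = {}
    for c in cells:
        frac.setdefault(c.substrate, []).append(c.present)
    col_order = sorted(
        frac, key=lambda name: (-(sum(frac[name]) / len(frac[name])), name)
    )
    return row_order, col_order


def cells_to_rows(cells: Sequence[ProfileCell]) -> list[dict]:
    rows = []
    for c in cells:
        rows.append(
            {
                "substrate": c.substrate,
                "species": c.species,
                "raw_score": c.raw_score,
                "alignment_length": c.alignment_length,
                "conservation_bits_per_col": round(c.conservation, 6),
                "coverage": round(c.coverage, 6),
                "present": c.present,
                "k_conserved": ""
                if not c.k_conserved
                else ";".join(f"K{p}={v}" for p, v in sorted(c.k_conserved.items())),
                "best_hit": c.best_hit or "",
            }
        )
    return rows
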