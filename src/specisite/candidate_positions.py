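"""Filtering workflow that reduces catalytic-domain positions to a small
candidate set of putative specificity-determining residues.

The scientific idea: residues controlling substrate scope are
*semiconserved* — conserved within major clades but divergent between
them — solvent-exposed, and often spatially clustered near functional
regions.  Each alignment column mapped to the reference is scored for
Shannon entropy (over the 20 amino acids, and over 5 physicochemical
classes), clade divergence ``D``, gap content and surface accessibility;
configurable filters combine these into a candidate verdict, and the
candidates are grouped by single-linkage clustering on representative-atom
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from specisite.core_io import (
    AMINO_ACIDS,
    AA_INDEX,
    GAP,
    MultipleAlignment,
    ResidueAnnotation,
)

#: Five-class physicochemical partition of the amino acids.
PHYSICOCHEMICAL_CLASSES: dict[str, str] = {
    "hydrophobic": "AVLIMFWC",
    "polar": "STNQYG",
    "positive": "KRH",
    "negative": "DE",
    "special": "P",
}

_CLASS_OF = {
    aa: name for name, members in PHYSICOCHEMICAL_CLASSES.items() for aa in members
}
_CLASS_NAMES = list(PHYSICOCHEMICAL_CLASSES)

KNOWN_FILTERS = (
    "gap_fraction_max",
    "entropy_window",
    "class_conservation",
    "rsa_min",
    "divergence_min",
)


class ConfigError(ValueError):
    """Unknown or inconsistent filter configuration."""


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


@dataclass
class ColumnProfile:
    """Composition summary of one mapped alignment column."""

    residue_number: int
    counts: np.ndarray  # 20-vector, gap-excluded
    p: np.ndarray  # frequencies, gap-excluded
    H: float  # Shannon entropy, bits
    H_class: float  # entropy over physicochemical classes, bits
    gap_fraction: float


@dataclass
class CladeDivergence:
    """Between-clade divergence of one column.

    ``D = min(f_a, f_b)`` when the two clade consensus (modal) residues
    differ, else 0; frequencies are gap-excluded within each clade.  A
    high ``D`` means each clade is internally consistent but the clades
    disagree — the signature of a specificity-switch position.
    """

    residue_number: int
    consensus_by_clade: dict[str, tuple[str, float]]
    D: Optional[float]  # None when a clade has too few observations


@dataclass
class PositionReport:
    residue_number: int
    profile: ColumnProfile
    divergence: Optional[CladeDivergence] = None
    rsa: Optional[float] = None
    passed_filters: dict[str, bool] = field(default_factory=dict)
    cluster_id: Optional[int] = None

    @property
    def is_candidate(self) -> bool:
        return bool(self.passed_filters) and all(self.passed_filters.values())


@dataclass
class FilterConfig:
    """Thresholds for the candidate filters.

    The entropy window keeps *semiconserved* columns: neither invariant
    (H below the window) nor hypervariable (H above it).  The class
    filter, with polarity ``"within"``, keeps columns whose variation
    stays inside one physicochemical class (H_class small); polarity
    ``"across"`` inverts this to demand chemistry-changing variation —
    the default, since substrate-specificity switches typically change
    residue chemistry.  ``divergence_min = 0.8`` asks for a strong
    (>= 80%) but different consensus in each clade.
    """

    gap_fraction_max: float = 0.5
    entropy_window: tuple[float, float] = (0.3, 2.5)
    class_max: float = 0.5
    class_polarity: str = "across"  # "within" | "across"
    rsa_min: float = 0.2
    divergence_min: float = 0.8
    enabled: tuple[str, ...] = KNOWN_FILTERS

    def __post_init__(self) -> None:
        for name in self.enabled:
            if name not in KNOWN_FILTERS:
                raise ConfigError(
                    f"unknown filter {name!r}; known: {KNOWN_FILTERS}"
                )
        if self.class_polarity not in ("within", "across"):
            raise ConfigError("class_polarity must be 'within' or 'across'")


def column_counts(alignment: MultipleAlignment, residue_number: int) -> np.ndarray:
    col = alignment.column(alignment.column_for_residue(residue_number))
    counts = np.zeros(20)
    for c in col:
        if c != GAP:
            counts[AA_INDEX[c]] += 1
    return counts


def column_entropy(
    alignment: MultipleAlignment, residue_number: int
) -> ColumnProfile:
    """Shannon entropy of a mapped column, in bits, gaps excluded.

    ``H = -sum_a p_a log2 p_a`` over amino acids; ``H_class`` is computed
    identically over the 5-class physicochemical partition, so
    ``H_class <= H`` always (coarsening cannot increase entropy).
    """
    col = alignment.column(alignment.column_for_residue(residue_number))
    counts = np.zeros(20)
    class_counts = np.zeros(len(_CLASS_NAMES))
    n_gap = 0
    for c in col:
        if c == GAP:
            n_gap += 1
        else:
            counts[AA_INDEX[c]] += 1
            class_counts[_CLASS_NAMES.index(_CLASS_OF[c])] += 1
    n = counts.sum()
    if n == 0:
        raise ValueError(
            f"no observations: column for residue {residue_number} is all-gap"
        )
    return ColumnProfile(
        residue_number=residue_number,
        counts=counts,
        p=counts / n,
        H=_entropy_bits(counts),
        H_class=_entropy_bits(class_counts),
        gap_fraction=n_gap / len(col),
    )


def clade_divergence(
    alignment: MultipleAlignment,
    residue_number: int,
    clade_a: str,
    clade_b: str,
    min_obs: int = 2,
) -> CladeDivergence:
    """Score how consistently two clades prefer different residues.

    For each clade the modal (consensus) residue and its gap-excluded
    frequency ``f`` are computed; ``D = min(f_a, f_b)`` when the modal
    residues differ, else 0.  ``D`` is ``None`` (excluded from ranking)
    when either clade has fewer than ``min_obs`` non-gap observations.
    Ties for the mode are broken alphabetically, which makes the score
    deterministic and symmetric in clade order.
    """
    clades = alignment.clades()
    for clade in (clade_a, clade_b):
        if clade not in clades:
            raise KeyError(f"clade {clade!r} absent from alignment")
    col_idx = alignment.column_for_residue(residue_number)
    consensus: dict[str, tuple[str, float]] = {}
    ok = True
    for clade in (clade_a, clade_b):
        members = set(clades[clade])
        counts = np.zeros(20)
        for s in alignment.sequences:
            if s.id in members and s.residues[col_idx] != GAP:
                counts[AA_INDEX[s.residues[col_idx]]] += 1
        n = counts.sum()
        if n < min_obs:
            ok = False
            continue
        best = int(np.argmax(counts))  # argmax ties -> lowest index = alphabetical
        consensus[clade] = (AMINO_ACIDS[best], counts[best] / n)
    if not ok:
        return CladeDivergence(residue_number, consensus, None)
    (ra, fa), (rb, fb) = consensus[clade_a], consensus[clade_b]
    D = min(fa, fb) if ra != rb else 0.0
    return CladeDivergence(residue_number, consensus, D)


def build_reports(
    alignment: MultipleAlignment,
    clade_a: str,
    clade_b: str,
    annotations: Optional[Sequence[ResidueAnnotation]] = None,
) -> list[PositionReport]:
    """Profile every mapped column: entropy, divergence, accessibility."""
    rsa_of = {}
    if annotations:
        rsa_of = {a.residue_number: a.rsa for a in annotations if a.rsa is not None}
    reports = []
    for num in alignment.mapped_residue_numbers():
        profile = column_entropy(alignment, num)
        div = clade_divergence(alignment, num, clade_a, clade_b)
        reports.append(
            PositionReport(
                residue_number=num,
                profile=profile,
                divergence=div,
                rsa=rsa_of.get(num),
            )
        )
    return reports


def apply_filters(
    reports: list[PositionReport], config: FilterConfig
) -> list[PositionReport]:
    """Attach per-filter verdicts; a candidate passes every enabled filter.

    Filters are independent (order-free); a missing measurement (no RSA,
    undefined D) fails the corresponding filter rather than passing
    silently.
    """
    lo, hi = config.entropy_window
    for r in reports:
        verdicts: dict[str, bool] = {}
        for name in config.enabled:
            if name == "gap_fraction_max":
                verdicts[name] = r.profile.gap_fraction <= config.gap_fraction_max
            elif name == "entropy_window":
                verdicts[name] = lo <= r.profile.H <= hi
            elif name == "class_conservation":
                within = r.profile.H_class <= config.class_max
                verdicts[name] = within if config.class_polarity == "within" else not within
            elif name == "rsa_min":
                verdicts[name] = r.rsa is not None and r.rsa >= config.rsa_min
            elif name == "divergence_min":
                verdicts[name] = (
                    r.divergence is not None
                    and r.divergence.D is not None
                    and r.divergence.D >= config.divergence_min
                )
        r.passed_filters = verdicts
    return reports


def cluster_positions(
    candidates: list[PositionReport],
    annotations: Sequence[ResidueAnnotation],
    cutoff_A: float = 10.0,
) -> list[list[int]]:
    """Single-linkage clustering of candidate residues in 3-D space.

    Replaces by a deterministic rule the by-eye grouping of candidates
    into proximal pairs/quadruples near functional regions.  Returns
    clusters of size >= 2 (residue-number lists, sorted); assigns
    ``cluster_id`` on the reports.  Candidates without coordinates are
    excluded with a warning attribute left unset.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    coord_of = {
        a.residue_number: a.coord for a in annotations if a.coord is not None
    }
    usable = [r for r in candidates if r.residue_number in coord_of]
    if len(usable) == 0:
        return []
    if len(usable) == 1:
        usable[0].cluster_id = None
        return []
    X = np.array([coord_of[r.residue_number] for r in usable])
    Z = linkage(pdist(X), method="single")
    labels = fcluster(Z, t=cutoff_A, criterion="distance")
    groups: dict[int, list[PositionReport]] = {}
    for r, lab in zip(usable, labels):
        groups.setdefault(int(lab), []).append(r)
    clusters = []
    next_id = 1
    for lab in sorted(groups, key=lambda k: min(r.residue_number for r in groups[k])):
        members = groups[lab]
        if len(members) >= 2:
            for r in members:
                r.cluster_id = next_id
            clusters.append(sorted(r.residue_number for r in members))
            next_id += 1
        else:
            members[0].cluster_id = None
    return clusters


def reports_to_rows(reports: list[PositionReport]) -> list[dict]:
    """Flatten reports for TSV/DataFrame output."""
    rows = []
    for r in reports:
        row: dict = {
            "residue_number": r.residue_number,
            "H": round(r.profile.H, 6),
            "H_class": round(r.profile.H_class, 6),
            "gap_fraction": round(r.profile.gap_fraction, 6),
            "rsa": r.rsa,
            "D": None if r.divergence is None else r.divergence.D,
            "candidate": r.is_candidate,
            "cluster_id": r.cluster_id,
        }
        if r.divergence is not None:
            for clade, (res, f) in r.divergence.consensus_by_clade.items():
                row[f"consensus_{clade}"] = res
                row[f"freq_{clade}"] = round(f, 6)
        for name, ok in r.passed_filters.items():
            row[f"pass_{name}"] = ok
        rows.append(row)
    return rows
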