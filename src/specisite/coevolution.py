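"""Co-evolving position pairs from a protein alignment.

Coupling is measured by mutual information (MI, in bits) between column
pairs, corrected for shared background (phylogeny, per-column entropy)
with the average-product correction (APC), and reported on a mean-scaled
convention: APC-corrected couplings are divided by the mean of the
positive off-diagonal entries, so a score of 1 marks the average pair
and strongly co-evolving pairs score well above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from specisite.core_io import MultipleAlignment


@dataclass
class CouplingMatrix:
    positions: list[int]  # residue numbers
    MI: np.ndarray  # symmetric, bits; diag = column entropy
    MIp: np.ndarray  # APC-corrected
    scaled: np.ndarray  # MIp / mean(positive off-diagonal MIp)

    def pair_index(self, i: int, j: int) -> tuple[int, int]:
        return self.positions.index(i), self.positions.index(j)

    def scaled_score(self, i: int, j: int) -> float:
        a, b = self.pair_index(i, j)
        return float(self.scaled[a, b])


def _joint_counts(code: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs joint amino-acid counts with pairwise gap deletion.

    ``code`` is (n_seq, n_col) with gap = 20.  Returns ``C`` of shape
    (n_col, n_col, 20, 20) and ``n`` of shape (n_col, n_col) — the number
    of sequences non-gapped at both columns of each pair.
    """
    n_seq, n_col = code.shape
    onehot = np.zeros((n_col, 20, n_seq), dtype=np.float64)
    for a in range(20):
        onehot[:, a, :] = (code.T == a)
    flat = onehot.reshape(n_col * 20, n_seq)
    C = (flat @ flat.T).reshape(n_col, 20, n_col, 20).transpose(0, 2, 1, 3)
    nongap = (code != 20).astype(np.float64)  # (n_seq, n_col)
    n = nongap.T @ nongap
    return C, n


def mi_matrix(
    alignment: MultipleAlignment,
    positions: list[int] | None = None,
    min_pairs: int = 10,
) -> tuple[list[int], np.ndarray]:
    """Pairwise mutual information (bits) between mapped columns.

    For each pair, rows gapped at either column are dropped and
    ``MI = H_i + H_j - H_ij`` is computed from the pairwise-complete
    joint counts.  The diagonal holds the per-column entropy.  Pairs with
    fewer than ``min_pairs`` complete rows are set to NaN and excluded
    downstream, with a warning.
    """
    if positions is None:
        positions = alignment.mapped_residue_numbers()
    cols = [alignment.column_for_residue(p) for p in positions]
    code = alignment.to_matrix()[:, cols]
    C, n = _joint_counts(code)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = C / n[:, :, None, None]
        Pi = P.sum(axis=3)  # marginal of first column within the pair
        Pj = P.sum(axis=2)

        def h(p: np.ndarray, axes: tuple) -> np.ndarray:
            t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
            return -t.sum(axis=axes)

        MI = h(Pi, (2,)) + h(Pj, (2,)) - h(P, (2, 3))
    bad = n < min_pairs
    if bad.any():
        warnings.warn(
            f"{int(bad.sum() - np.trace(bad))} column pairs have fewer than "
            f"{min_pairs} complete rows; excluded (NaN)"
        )
        MI[bad] = np.nan
    MI = np.clip(MI, 0.0, None)  # NaN propagates through clip
    # exact symmetry despite floating point
    MI = (MI + MI.T) / 2.0
    return positions, MI


def mutual_information(
    alignment: MultipleAlignment, i: int, j: int, min_pairs: int = 10
) -> float:
    """MI (bits) between the columns for residue numbers ``i`` and ``j``."""
    positions, MI = mi_matrix(alignment, [i, j], min_pairs=min_pairs)
    val = MI[0, 1]
    if np.isnan(val):
        raise ValueError(
            f"insufficient paired observations for columns {i}, {j}"
        )
    return float(val)


def apc_and_scale(MI: np.ndarray, positions: list[int]) -> CouplingMatrix:
    """Average-product correction and mean-scaling of an MI matrix.

    ``MIp(i,j) = MI(i,j) - mean_i * mean_j / grand_mean`` with means taken
    over off-diagonal entries; the correction removes the separable
    background every column shares (entropy, phylogenetic signal).  The
    scaled matrix divides MIp by the mean of its positive off-diagonal
    entries so that 1 is the average coupling.
    """
    MI = np.asarray(MI, dtype=float)
    k = MI.shape[0]
    if k < 3:
        raise ValueError("need at least 3 positions for APC")
    if not np.allclose(MI, MI.T, equal_nan=True):
        raise ValueError("MI matrix must be symmetric")
    off = ~np.eye(k, dtype=bool)
    valid = off & ~np.isnan(MI)
    if not valid.any() or np.nanmax(np.abs(MI[valid])) == 0:
        raise ValueError("no signal: all off-diagonal MI are zero or missing")
    row_mean = np.array(
        [MI[i, valid[i]].mean() if valid[i].any() else np.nan for i in range(k)]
    )
    grand = MI[valid].mean()
    MIp = MI - np.outer(row_mean, row_mean) / grand
    MIp[~valid] = np.nan
    np.fill_diagonal(MIp, np.nan)
    pos_entries = MIp[off & (MIp > 0)]
    if pos_entries.size == 0:
        if np.nanmax(np.abs(MIp[valid])) < 1e-9:
            # perfectly uniform background: APC removed everything
            scaled = np.zeros_like(MIp)
            scaled[~valid] = np.nan
            return CouplingMatrix(
                positions=list(positions), MI=MI, MIp=MIp, scaled=scaled
            )
        raise ValueError("no signal: no positive APC-corrected couplings")
    scaled = MIp / pos_entries.mean()
    return CouplingMatrix(positions=list(positions), MI=MI, MIp=MIp, scaled=scaled)


def compute_couplings(
    alignment: MultipleAlignment,
    positions: list[int] | None = None,
    min_pairs: int = 10,
) -> CouplingMatrix:
    """MI -> APC -> scaled, in one call."""
    positions, MI = mi_matrix(alignment, positions, min_pairs=min_pairs)
    return apc_and_scale(MI, positions)


def report_couplings(
    cm: CouplingMatrix,
    candidates: list[int] | None = None,
    threshold: float = 1.0,
) -> list[tuple[int, int, float]]:
    """Pairs with scaled coupling >= threshold, ranked descending.

    When ``candidates`` is given, both members of a pair must be in it.
    """
    out = []
    k = len(cm.positions)
    cand = None if candidates is None else set(candidates)
    for a in range(k):
        for b in range(a + 1, k):
            s = cm.scaled[a, b]
            if np.isnan(s) or s < threshold:
                continue
            i, j = cm.positions[a], cm.positions[b]
            if cand is not None and (i not in cand or j not in cand):
                continue
            out.append((i, j, float(s)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out
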