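"""Marginal ancestral sequence reconstruction on a fixed rooted tree.

Given an alignment, a rooted tree with branch lengths (expected
substitutions/site) and a reversible amino-acid substitution model, this
module computes site log-likelihoods by Felsenstein's pruning algorithm
and per-node marginal posteriors by the standard up-down (inside-outside)
message passing.  Posteriors at focal positions feed two downstream
products: text "sequence logos" (residues ranked by posterior) and
ancestor-guided combinatorial variant panels, where a position whose
top (MAP) state is uncertain contributes its two most probable states.

The default model uses Poisson (equal) exchangeabilities with stationary
frequencies estimated from the alignment; empirical matrices (LG, WAG,
...) can be loaded from PAML-format rate files.  A single rate applies
across sites and gaps are treated as missing data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from specisite.core_io import (
    AMINO_ACIDS,
    AA_INDEX,
    GAP,
    MultipleAlignment,
    PhyloTree,
)


@dataclass
class SubstitutionModel:
    """Time-reversible substitution model ``Q_ij = s_ij * pi_j``.

    ``exchangeabilities`` is a symmetric non-negative matrix (diagonal
    ignored); ``pi`` the stationary distribution.  ``Q`` is normalized so
    the expected rate ``-sum_i pi_i Q_ii`` equals 1, which calibrates
    branch lengths in expected substitutions per site.  Transition
    matrices ``P(t) = exp(Qt)`` are computed by spectral decomposition of
    the symmetrized generator, which is exact and cheap for reversible
    models.
    """

    exchangeabilities: np.ndarray
    pi: np.ndarray
    n_states: int = field(init=False)
    Q: np.ndarray = field(init=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _U: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape[0] != S.shape[1] or S.shape[0] != pi.size:
            raise ValueError("shape mismatch between exchangeabilities and pi")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi must be positive and sum to 1")
        self.n_states = pi.size
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.sum(pi * np.diag(Q))
        if rate <= 0:
            raise ValueError("degenerate model: zero substitution rate")
        Q /= rate
        self.pi = pi
        self.Q = Q
        # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._U = V
        self._d = d

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Qt)``; rows sum to 1."""
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        E = self._U * np.exp(self._eigvals * t)[None, :]
        B = E @ self._U.T
        P = (B / self._d[:, None]) * self._d[None, :]
        return np.clip(P, 0.0, None)

    @classmethod
    def poisson(cls, pi: Optional[np.ndarray] = None) -> "SubstitutionModel":
        """Equal exchangeabilities; uniform pi unless given."""
        if pi is None:
            pi = np.full(20, 1 / 20)
        n = len(pi)
        S = np.ones((n, n))
        return cls(exchangeabilities=S, pi=np.asarray(pi, float))

    @classmethod
    def from_alignment(cls, alignment: MultipleAlignment) -> "SubstitutionModel":
        """Poisson exchangeabilities with empirical frequencies (plus a
        small floor so every state has positive stationary mass)."""
        counts = np.ones(20)  # +1 floor
        for s in alignment.sequences:
            for c in s.residues:
                if c != GAP:
                    counts[AA_INDEX[c]] += 1
        return cls.poisson(counts / counts.sum())

    @classmethod
    def from_paml(cls, path: str | Path) -> "SubstitutionModel":
        """Read a PAML-format amino-acid rate file (lower-triangle
        exchangeabilities, then 20 stationary frequencies)."""
        values = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if line:
                values.extend(float(x) for x in line.split())
        if len(values) < 190 + 20:
            raise ValueError("PAML file lacks 190 exchangeabilities + 20 frequencies")
        S = np.zeros((20, 20))
        k = 0
        for i in range(1, 20):
            for j in range(i):
                S[i, j] = S[j, i] = values[k]
                k += 1
        pi = np.array(values[190:210])
        return cls(exchangeabilities=S, pi=pi / pi.sum())


@dataclass
class AncestralPosterior:
    """Marginal posterior state distribution at one node and site."""

    node: str
    site: int  # reference residue number
    P: np.ndarray  # sums to 1
    alphabet: str = AMINO_ACIDS

    @property
    def map_state(self) -> str:
        return self.alphabet[int(np.argmax(self.P))]

    @property
    def map_probability(self) -> float:
        return float(self.P.max())

    @property
    def second_state(self) -> str:
        order = np.argsort(-self.P, kind="stable")
        return self.alphabet[int(order[1])]

    @property
    def second_probability(self) -> float:
        order = np.argsort(-self.P, kind="stable")
        return float(self.P[order[1]])


def _pattern_vector(char: str, n_states: int, alphabet: str) -> np.ndarray:
    v = np.zeros(n_states)
    if char == GAP:
        v[:] = 1.0  # missing data
    else:
        v[alphabet.index(char)] = 1.0
    return v


def _partials(
    tree: PhyloTree,
    pattern: dict[str, str],
    model: SubstitutionModel,
    alphabet: str,
) -> dict[int, np.ndarray]:
    """Post-order partial (conditional) likelihood vectors, keyed by id(node)."""
    down: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            if name not in pattern:
                raise ValueError(f"tip {name!r} missing from site pattern")
            down[id(node)] = _pattern_vector(pattern[name], model.n_states, alphabet)
        else:
            L = np.ones(model.n_states)
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                P = model.transition_matrix(t)
                L = L * (P @ down[id(child)])
            down[id(node)] = L
    return down


def site_likelihood(
    tree: PhyloTree,
    pattern: dict[str, str],
    model: SubstitutionModel,
    alphabet: str = AMINO_ACIDS,
) -> float:
    """Felsenstein-pruning log-likelihood of one site pattern.

    ``pattern`` maps tip name to residue character; gaps are missing
    data (all-ones partial vector).
    """
    down = _partials(tree, pattern, model, alphabet)
    root_L = down[id(tree.root)]
    lik = float(model.pi @ root_L)
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


def _outside_messages(
    tree: PhyloTree,
    down: dict[int, np.ndarray],
    model: SubstitutionModel,
) -> dict[int, np.ndarray]:
    """Pre-order 'rest of tree' vectors: O_v(x) is the likelihood of all
    data outside the subtree of v, given state x at v, weighted so the
    root case is pi."""
    out: dict[int, np.ndarray] = {id(tree.root): model.pi.copy()}
    for node in tree.tree.preorder_node_iter():
        o_v = out[id(node)]
        children = node.child_nodes()
        for child in children:
            sib_prod = np.ones(model.n_states)
            for sib in children:
                if sib is child:
                    continue
                P_s = model.transition_matrix(sib.edge.length or 0.0)
                sib_prod *= P_s @ down[id(sib)]
            P_c = model.transition_matrix(child.edge.length or 0.0)
            out[id(child)] = (o_v * sib_prod) @ P_c
    return out


def marginal_posteriors(
    tree: PhyloTree,
    alignment: MultipleAlignment,
    model: SubstitutionModel,
    nodes: Sequence[str],
    sites: Sequence[int],
    alphabet: str = AMINO_ACIDS,
) -> list[AncestralPosterior]:
    """Marginal posterior state distributions at internal nodes.

    For node v and state x, ``P(x | data) ∝ down_v(x) * O_v(x)`` where
    ``down_v`` is the pruning partial below v and ``O_v`` the outside
    message (which already carries the stationary prior, so at the root
    the product reduces to ``pi_x * L_root(x)``); normalized per site.
    """
    tree.check_tips_match(alignment)
    node_objs = {name: tree.node(name) for name in nodes}  # KeyError if unknown
    results = []
    for site in sites:
        col = alignment.column_for_residue(site)
        pattern = {s.id: s.residues[col] for s in alignment.sequences}
        down = _partials(tree, pattern, model, alphabet)
        out = _outside_messages(tree, down, model)
        for name in nodes:
            v = node_objs[name]
            raw = down[id(v)] * out[id(v)]
            total = raw.sum()
            if total <= 0:
                raise ValueError(f"zero likelihood at node {name}, site {site}")
            results.append(
                AncestralPosterior(node=name, site=site, P=raw / total, alphabet=alphabet)
            )
    return results


def enumeration_site_posteriors(
    tree: PhyloTree,
    pattern: dict[str, str],
    model: SubstitutionModel,
    alphabet: str = AMINO_ACIDS,
) -> tuple[float, dict[str, np.ndarray]]:
    """Brute-force likelihood and node posteriors by summing over every
    assignment of states to internal nodes.

    Exponential in node count — usable only on tiny trees; serves as the
    independent oracle for the pruning implementation.
    """
    n = model.n_states
    internal = list(tree.tree.postorder_internal_node_iter())
    tips = [leaf for leaf in tree.tree.leaf_node_iter()]
    total = 0.0
    node_mass = {v.label: np.zeros(n) for v in internal}
    for assignment in itertools.product(range(n), repeat=len(internal)):
        state_of = {id(v): s for v, s in zip(internal, assignment)}
        w = model.pi[state_of[id(tree.root)]]
        for v in internal:
            P_edges = 1.0
            for child in v.child_nodes():
                P = model.transition_matrix(child.edge.length or 0.0)
                if child.is_leaf():
                    vec = _pattern_vector(pattern[child.taxon.label], n, alphabet)
                    P_edges *= float(P[state_of[id(v)]] @ vec)
                else:
                    P_edges *= P[state_of[id(v)], state_of[id(child)]]
            w *= P_edges
        total += w
        for v, s in zip(internal, assignment):
            node_mass[v.label][s] += w
    posteriors = {k: v / total for k, v in node_mass.items()}
    return float(np.log(total)), posteriors


def posterior_logo(posteriors: Sequence[AncestralPosterior]) -> list[dict]:
    """Text logo: per node and site, residues sorted by posterior
    probability (descending; alphabetical on ties)."""
    rows = []
    for ap in posteriors:
        order = sorted(range(len(ap.P)), key=lambda i: (-ap.P[i], ap.alphabet[i]))
        for rank, idx in enumerate(order, start=1):
            if ap.P[idx] <= 0:
                continue
            rows.append(
                {
                    "node": ap.node,
                    "site": ap.site,
                    "rank": rank,
                    "residue": ap.alphabet[idx],
                    "probability": float(ap.P[idx]),
                }
            )
    return rows


@dataclass
class VariantPanel:
    """Combinatorial mutant panel guided by ancestral posteriors at one node."""

    ancestor: str
    focal_positions: list[int]
    variants: list[dict[int, str]]  # position -> admitted residue
    provenance: list[dict[int, float]]  # position -> posterior of that residue
    reference_residues: dict[int, str]

    def mutation_strings(self) -> list[str]:
        """Render each variant as e.g. ``"N417A/R424E"``; positions equal
        to the reference are omitted; the all-reference variant renders
        as ``"WT"``."""
        out = []
        for var in self.variants:
            muts = [
                f"{self.reference_residues[p]}{p}{r}"
                for p, r in sorted(var.items())
                if r != self.reference_residues[p]
            ]
            out.append("/".join(muts) if muts else "WT")
        return out


class PanelTooLargeError(ValueError):
    pass


def enumerate_variants(
    posteriors: Sequence[AncestralPosterior],
    focal_positions: Sequence[int],
    reference: MultipleAlignment,
    ambiguity_threshold: float = 0.8,
    max_variants: int = 8,
) -> VariantPanel:
    """Build the combinatorial mutant panel for one ancestor.

    Per focal position the admitted states are {MAP} when the MAP
    posterior reaches ``ambiguity_threshold``, else {MAP, second-best}
    (never three).  The Cartesian product across positions gives the
    panel; each variant is rendered against the reference sequence.
    """
    if not (0.5 < ambiguity_threshold <= 1.0):
        raise ValueError("ambiguity_threshold must be in (0.5, 1]")
    by_site = {ap.site: ap for ap in posteriors}
    nodes = {ap.node for ap in posteriors}
    if len(nodes) != 1:
        raise ValueError("posteriors must all come from one ancestor node")
    ref_seq = reference.reference_sequence()
    ref_res = {}
    admitted: list[list[tuple[str, float]]] = []
    for p in focal_positions:
        if p not in by_site:
            raise KeyError(f"no posterior supplied for focal position {p}")
        ap = by_site[p]
        ref_res[p] = ref_seq.residues[reference.column_for_residue(p)]
        states = [(ap.map_state, ap.map_probability)]
        if ap.map_probability < ambiguity_threshold:
            states.append((ap.second_state, ap.second_probability))
        admitted.append(states)
    n_var = int(np.prod([len(s) for s in admitted]))
    if n_var > max_variants:
        raise PanelTooLargeError(
            f"panel of {n_var} variants exceeds cap {max_variants}; raise "
            "ambiguity_threshold or the cap"
        )
    variants, provenance = [], []
    for combo in itertools.product(*admitted):
        variants.append({p: r for p, (r, _) in zip(focal_positions, combo)})
        provenance.append({p: q for p, (_, q) in zip(focal_positions, combo)})
    return VariantPanel(
        ancestor=nodes.pop(),
        focal_positions=list(focal_positions),
        variants=variants,
        provenance=provenance,
        reference_residues=ref_res,
    )
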