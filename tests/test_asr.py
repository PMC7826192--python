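import numpy as np
import pytest

from specisite.asr import (
    AncestralPosterior,
    PanelTooLargeError,
    SubstitutionModel,
    enumerate_variants,
    enumeration_site_posteriors,
    marginal_posteriors,
    posterior_logo,
    site_likelihood,
)
from specisite.core_io import AlignedSequence, MultipleAlignment, tree_from_newick
from specisite.synthetic_data import SimulationConfig, simulate_alignment

ALPHA4 = "ACDE"


def _random_model(rng, n=4):
    S = rng.uniform(0.2, 2.0, size=(n, n))
    S = (S + S.T) / 2
    pi = rng.dirichlet(np.full(n, 5.0))
    return SubstitutionModel(exchangeabilities=S, pi=pi)


def _random_four_tip_tree(rng):
    t = rng.uniform(0.05, 1.5, size=6)
    if rng.random() < 0.5:
        nwk = f"((A:{t[0]},B:{t[1]})X:{t[2]},(C:{t[3]},D:{t[4]})Y:{t[5]})R;"
    else:
        nwk = f"(((A:{t[0]},B:{t[1]})X:{t[2]},C:{t[3]})Y:{t[4]},D:{t[5]})R;"
    return tree_from_newick(nwk)


class TestSubstitutionModel:
    def test_rate_matrix_invariants(self, rng):
        m = _random_model(rng, n=20)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        # detailed balance
        assert np.allclose(m.pi[:, None] * m.Q, (m.pi[:, None] * m.Q).T, atol=1e-12)
        # mean rate one
        assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0, abs=1e-12)

    def test_transition_matrix_limits(self, rng):
        m = _random_model(rng)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-12)
        P = m.transition_matrix(0.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        # long-time limit approaches stationarity
        assert np.allclose(m.transition_matrix(500.0), np.tile(m.pi, (4, 1)), atol=1e-8)

    def test_paml_round_trip(self, tmp_path, rng):
        S = rng.uniform(0.1, 3.0, size=(20, 20))
        S = (S + S.T) / 2
        pi = rng.dirichlet(np.full(20, 10.0))
        lines = []
        for i in range(1, 20):
            lines.append(" ".join(f"{S[i, j]:.6f}" for j in range(i)))
        lines.append("")
        lines.append(" ".join(f"{p:.6f}" for p in pi))
        p = tmp_path / "rates.dat"
        p.write_text("\n".join(lines) + "\n")
        m = SubstitutionModel.from_paml(p)
        assert np.allclose(m.pi, pi / pi.sum(), atol=1e-6)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-10)


class TestPruning:
    def test_zero_branches_identical_tips_reduce_to_pi(self):
        tree = tree_from_newick("((A:0.0,B:0.0):0.0,C:0.0)R;")
        m = SubstitutionModel.poisson(np.array([0.4, 0.3, 0.2, 0.1]))
        ll = site_likelihood(tree, {"A": "A", "B": "A", "C": "A"}, m, alphabet=ALPHA4)
        assert ll == pytest.approx(np.log(0.4), abs=1e-12)

    def test_all_gaps_give_likelihood_one(self, four_tip_tree):
        m = SubstitutionModel.poisson(np.full(4, 0.25))
        ll = site_likelihood(
            four_tip_tree, {n: "-" for n in "ABCD"}, m, alphabet=ALPHA4
        )
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        """Pruning log-likelihood and marginal posteriors equal exhaustive
        enumeration over internal-state assignments on 4-tip instances."""
        for _ in range(20):
            tree = _random_four_tip_tree(rng)
            m = _random_model(rng)
            pattern = {n: ALPHA4[rng.integers(4)] for n in "ABCD"}
            ll = site_likelihood(tree, pattern, m, alphabet=ALPHA4)
            ll_enum, post_enum = enumeration_site_posteriors(
                tree, pattern, m, alphabet=ALPHA4
            )
            assert ll == pytest.approx(ll_enum, abs=1e-10)
            seqs = [AlignedSequence(n, pattern[n]) for n in "ABCD"]
            aln = MultipleAlignment(sequences=seqs, reference_id="A")
            for node in ("X", "Y", "R"):
                ap = marginal_posteriors(
                    tree, aln, m, [node], [1], alphabet=ALPHA4
                )[0]
                assert np.max(np.abs(ap.P - post_enum[node])) < 1e-10

    def test_likelihood_invariant_to_rerooting(self, rng):
        """Reversibility: the pruning likelihood does not depend on root
        placement along any branch."""
        tree = _random_four_tip_tree(rng)
        m = _random_model(rng)
        pattern = {"A": "A", "B": "C", "C": "D", "D": "A"}
        base = site_likelihood(tree, pattern, m, alphabet=ALPHA4)
        t2 = tree.clone()
        edge = t2.node("A").edge
        t2.tree.reroot_at_edge(edge, length1=edge.length / 2, length2=edge.length / 2)
        rerooted = site_likelihood(t2, pattern, m, alphabet=ALPHA4)
        assert rerooted == pytest.approx(base, abs=1e-10)

    def test_negative_branch_rejected(self, four_tip_tree):
        m = _random_model(np.random.default_rng(0))
        with pytest.raises(ValueError):
            m.transition_matrix(-0.1)

    def test_missing_tip_rejected(self, four_tip_tree):
        m = _random_model(np.random.default_rng(0))
        with pytest.raises(ValueError, match="missing"):
            site_likelihood(four_tip_tree, {"A": "A"}, m, alphabet=ALPHA4)


class TestMarginalPosteriors:
    def test_star_of_identical_tips_is_near_certain(self):
        tree = tree_from_newick("(A:0.02,B:0.02,C:0.02)R;")
        seqs = [AlignedSequence(n, "R") for n in "ABC"]
        aln = MultipleAlignment(sequences=seqs, reference_id="A")
        m = SubstitutionModel.poisson()
        ap = marginal_posteriors(tree, aln, m, ["R"], [1])[0]
        assert ap.map_state == "R"
        assert ap.map_probability > 0.99

    def test_posteriors_normalized_and_map_maximal(self, rng):
        cfg = SimulationConfig(seed=2, n_tips=16, n_sites=30)
        aln, tree, truth = simulate_alignment(cfg)
        m = SubstitutionModel.poisson()
        posts = marginal_posteriors(
            tree, aln, m, [truth.root_name], aln.mapped_residue_numbers()[:10]
        )
        for ap in posts:
            assert ap.P.sum() == pytest.approx(1.0, abs=1e-9)
            assert ap.map_probability >= ap.P.max() - 1e-15

    def test_unknown_node_rejected(self, toy_alignment):
        tree = tree_from_newick(
            "((a1:0.1,a2:0.1):0.1,((a3:0.1,b1:0.1):0.1,(b2:0.1,b3:0.1):0.1):0.1);"
        )
        m = SubstitutionModel.poisson()
        with pytest.raises(KeyError):
            marginal_posteriors(tree, toy_alignment, m, ["Anc999"], [1])

    def test_recovery_improves_as_tree_shrinks(self):
        """Mean posterior mass on the true root state rises monotonically
        as the simulated tree height drops."""
        m = SubstitutionModel.poisson()
        means = []
        for h in (2.0, 1.0, 0.25):
            cfg = SimulationConfig(seed=3, n_tips=32, tree_height=h)
            aln, tree, truth = simulate_alignment(cfg)
            sites = [
                s
                for s in aln.mapped_residue_numbers()
                if s not in truth.planted_divergent_sites
                and all(s not in p for p in truth.planted_coupled_pairs)
            ]
            posts = marginal_posteriors(tree, aln, m, [truth.root_name], sites)
            true_seq = truth.ancestral_sequences[truth.root_name]
            means.append(
                np.mean(
                    [ap.P[ap.alphabet.index(true_seq[ap.site - 1])] for ap in posts]
                )
            )
        assert means[0] < means[1] < means[2]


class TestLogoAndVariants:
    def _post(self, node, site, probs):
        P = np.zeros(20)
        for res, p in probs.items():
            P["ACDEFGHIKLMNPQRSTVWY".index(res)] = p
        return AncestralPosterior(node=node, site=site, P=P)

    def test_logo_rows_sorted_by_probability(self):
        rows = posterior_logo([self._post("n", 5, {"A": 0.6, "E": 0.4})])
        assert [(r["residue"], r["probability"]) for r in rows] == [
            ("A", 0.6),
            ("E", 0.4),
        ]

    def test_logo_ties_break_alphabetically(self):
        rows = posterior_logo([self._post("n", 5, {"W": 0.5, "C": 0.5})])
        assert [r["residue"] for r in rows] == ["C", "W"]

    def _ref(self, residues="RLNKF"):
        seqs = [
            AlignedSequence("ref", residues),
            AlignedSequence("o", residues),
        ]
        return MultipleAlignment(sequences=seqs, reference_id="ref")

    def test_unambiguous_reference_states_give_wild_type(self):
        ref = self._ref()
        posts = [
            self._post("anc", i + 1, {res: 1.0})
            for i, res in enumerate("RLNKF")
        ]
        panel = enumerate_variants(posts, [1, 2, 3, 4, 5], ref)
        assert panel.mutation_strings() == ["WT"]

    def test_two_ambiguous_positions_give_four_variants(self):
        ref = self._ref()
        posts = [
            self._post("anc", 1, {"A": 0.6, "R": 0.4}),
            self._post("anc", 2, {"E": 0.7, "L": 0.3}),
            self._post("anc", 3, {"N": 0.95}),
            self._post("anc", 4, {"K": 0.99}),
            self._post("anc", 5, {"F": 0.9}),
        ]
        panel = enumerate_variants(posts, [1, 2, 3, 4, 5], ref)
        muts = panel.mutation_strings()
        assert len(muts) == 4
        assert "R1A/L2E" in muts
        assert "WT" in muts  # the (R, L) combination equals the reference

    def test_panel_cap_enforced(self):
        ref = self._ref()
        posts = [
            self._post("anc", i + 1, {"A": 0.55, "C": 0.45}) for i in range(5)
        ]
        with pytest.raises(PanelTooLargeError):
            enumerate_variants(posts, [1, 2, 3, 4, 5], ref, max_variants=8)

    def test_threshold_validated(self):
        ref = self._ref()
        with pytest.raises(ValueError):
            enumerate_variants([], [], ref, ambiguity_threshold=0.4)
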