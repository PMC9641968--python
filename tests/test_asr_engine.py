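import numpy as np
import pytest

import ancsite as ac
from ancsite.io_phylo import TreeError
from ancsite.synthetic_data import SimulationSpec, random_topology
from conftest import brute_force_site

SMALL_TREES = [
    "(a:0.3,b:0.7);",
    "((a:0.2,b:0.35):0.15,c:0.4);",
    "((a:0.2,b:0.35):0.15,(c:0.4,d:0.1):0.25);",
    "(((a:0.1,b:0.3):0.2,c:0.5):0.12,(d:0.25,e:0.45):0.3);",
    "((((a:0.1,b:0.2):0.1,c:0.3):0.1,d:0.4):0.1,e:0.5);",
]


def _alignment_for(phy, seed):
    rng = np.random.default_rng(seed)
    labels = sorted(phy.leaf_labels)
    rows = ["".join(rng.choice(list(ac.AA_LETTERS), size=2)) for _ in labels]
    return ac.Alignment(ids=labels, rows=rows)


class TestSiteLogLikelihood:
    def test_single_leaf_closed_form(self, lg_uniform):
        # degenerate rooted 2-leaf tree with a missing partner reduces to pi
        phy = ac.read_newick("(a:0.0,b:0.0);")
        aln = ac.Alignment(ids=["a", "b"], rows=["A", "X"])
        expected = np.log(lg_uniform.pi[ac.AA_LETTERS.index("A")])
        assert ac.site_log_likelihood(phy, aln, lg_uniform, 1) == pytest.approx(expected)

    def test_zero_branches_equal_states(self, lg_uniform):
        phy = ac.read_newick("(a:0.0,b:0.0);")
        aln = ac.Alignment(ids=["a", "b"], rows=["H", "H"])
        expected = np.log(lg_uniform.pi[ac.AA_LETTERS.index("H")])
        assert ac.site_log_likelihood(phy, aln, lg_uniform, 1) == pytest.approx(expected)

    def test_leaf_without_alignment_row_errors(self, lg_uniform):
        phy = ac.read_newick("(a:0.1,b:0.1);")
        aln = ac.Alignment(ids=["a", "zzz"], rows=["A", "A"])
        with pytest.raises(TreeError, match="'b'"):
            ac.site_log_likelihood(phy, aln, lg_uniform, 1)

    @pytest.mark.parametrize("nwk", SMALL_TREES)
    def test_matches_brute_force_enumeration(self, nwk, lg_uniform):
        phy = ac.read_newick(nwk)
        aln = _alignment_for(phy, seed=11)
        for site in (1, 2):
            lik, _ = brute_force_site(phy, aln, lg_uniform, site)
            assert ac.site_log_likelihood(phy, aln, lg_uniform, site) == pytest.approx(
                np.log(lik), abs=1e-10
            )

    def test_root_placement_invariance(self, lg_gamma4):
        phy = ac.read_newick("((a:0.2,b:0.35):0.15,(c:0.4,d:0.1):0.25);")
        aln = _alignment_for(phy, seed=5)
        lls = []
        for og in [{"a"}, {"b"}, {"c"}, {"c", "d"}]:
            rooted = ac.root_on_outgroup(phy, og)
            lls.append(ac.log_likelihoods(rooted, aln, lg_gamma4))
        for other in lls[1:]:
            assert np.abs(other - lls[0]).max() < 1e-9


class TestMarginalASR:
    def test_uniform_data_zero_branches_certain(self, lg_uniform):
        phy = ac.read_newick("((a:0.0,b:0.0):0.0,(c:0.0,d:0.0):0.0);")
        aln = ac.Alignment(ids=list("abcd"), rows=["H"] * 4)
        table = ac.marginal_asr(phy, aln, lg_uniform, phy.tree.seed_node, node_id="r")
        assert table.residue_probs("r", 1)["H"] == pytest.approx(1.0)

    def test_infinite_branches_posterior_is_pi(self, lg_uniform):
        phy = ac.read_newick("((a:1e4,b:1e4):1e4,(c:1e4,d:1e4):1e4);")
        aln = ac.Alignment(ids=list("abcd"), rows=["A", "R", "N", "D"])
        table = ac.marginal_asr(phy, aln, lg_uniform, phy.tree.seed_node, node_id="r")
        assert np.abs(table.vector("r", 1) - lg_uniform.pi).max() < 1e-6

    def test_leaf_target_rejected(self, lg_uniform):
        phy = ac.read_newick("(a:0.1,b:0.1);")
        aln = ac.Alignment(ids=["a", "b"], rows=["A", "A"])
        with pytest.raises(TreeError, match="internal"):
            ac.marginal_asr(phy, aln, lg_uniform, phy.find_leaf("a"))

    @pytest.mark.parametrize("nwk", SMALL_TREES[1:])
    @pytest.mark.parametrize("model_fixture", ["lg_uniform", "lg_gamma4"])
    def test_matches_brute_force_posteriors(self, nwk, model_fixture, request):
        model = request.getfixturevalue(model_fixture)
        phy = ac.read_newick(nwk)
        aln = _alignment_for(phy, seed=23)
        _, oracle = brute_force_site(phy, aln, model, 1)
        for node, expected in oracle.items():
            got = ac.marginal_asr(phy, aln, model, node, sites=[1], node_id="n")
            assert np.abs(got.vector("n", 1) - expected).max() < 1e-9

    def test_posterior_invariant_to_original_rooting(self, lg_gamma4):
        phy = ac.read_newick("((a:0.2,b:0.35):0.15,(c:0.4,d:0.1):0.25);")
        aln = _alignment_for(phy, seed=9)
        posts = []
        for og in [{"a"}, {"b"}]:
            rooted = ac.root_on_outgroup(phy, og)
            node = ac.mrca(rooted, {"c", "d"})
            posts.append(
                ac.marginal_asr(rooted, aln, lg_gamma4, node, node_id="x").vector("x", 1)
            )
        assert np.abs(posts[0] - posts[1]).max() < 1e-9

    def test_gap_leaf_treated_as_missing(self, lg_uniform):
        # a gap leaf must not change the posterior relative to pruning it out
        full = ac.read_newick("((a:0.2,b:0.3):0.1,(c:0.25,d:0.15):0.2);")
        aln = ac.Alignment(ids=list("abcd"), rows=["A", "-", "R", "N"])
        node = ac.mrca(full, {"c", "d"})
        with_gap = ac.marginal_asr(full, aln, lg_uniform, node, node_id="x").vector("x", 1)
        _, oracle = brute_force_site(full, aln, lg_uniform, 1)
        assert np.abs(with_gap - oracle[node]).max() < 1e-9


class TestPipeline:
    def test_pipeline_output_is_valid_statetable(self, lg_uniform):
        rng = np.random.default_rng(0)
        spec = SimulationSpec(n_leaves=10, n_sites=30, model=lg_uniform, seed=4)
        aln, phy, _ = ac.simulate_alignment(spec)
        labels = phy.leaf_labels
        outgroup = {labels[0]}
        ingroup = set(labels) - outgroup
        table = ac.run_asr_pipeline(aln, phy, lg_uniform, outgroup, ingroup, node_id="Anc")
        assert table.sites("Anc") == list(range(1, 31))
        for site in table.sites("Anc"):
            assert table.vector("Anc", site).sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_monophyletic_outgroup_surfaces_rooting_error(self, lg_uniform):
        phy = ac.read_newick("(a:1,b:1,(c:1,d:1):2);")
        aln = ac.Alignment(ids=list("abcd"), rows=["A", "R", "N", "D"])
        with pytest.raises(TreeError, match="monophyletic"):
            ac.run_asr_pipeline(aln, phy, lg_uniform, {"a", "c"}, {"b", "d"})

    def test_composition_identity_with_direct_marginal(self, lg_uniform):
        phy = ac.read_newick("(a:0.3,b:0.2,(c:0.15,d:0.45):0.3);")
        aln = ac.Alignment(ids=list("abcd"), rows=["AC", "RY", "ND", "CW"])
        table = ac.run_asr_pipeline(aln, phy, lg_uniform, {"a"}, {"c", "d"}, node_id="Anc")
        rooted = ac.root_on_outgroup(phy, {"a"})
        node = ac.mrca(rooted, {"c", "d"})
        direct = ac.marginal_asr(rooted, aln, lg_uniform, node, node_id="Anc")
        for site in (1, 2):
            assert np.abs(table.vector("Anc", site) - direct.vector("Anc", site)).max() < 1e-12


class TestParameterRecovery:
    def test_accuracy_non_increasing_in_branch_scale(self, lg_gamma4):
        """Root-state recovery degrades as branches get longer (signal decays)."""
        rng = np.random.default_rng(7)
        base = random_topology(20, 0.3, rng)
        accuracies = []
        for scale in (0.01, 0.1, 1.0, 10.0):
            phy = base.clone()
            for e in phy.tree.preorder_edge_iter():
                if e.length is not None:
                    e.length *= scale
            spec = SimulationSpec(n_leaves=20, n_sites=500, model=lg_gamma4, tree=phy, seed=7)
            aln, tree, truth = ac.simulate_alignment(spec)
            table = ac.marginal_asr(tree, aln, lg_gamma4, tree.tree.seed_node, node_id="r")
            true_root = truth.sequences[truth.root_label]
            hits = sum(
                ac.AA_LETTERS[int(np.argmax(table.vector("r", s)))] == true_root[s - 1]
                for s in range(1, 501)
            )
            accuracies.append(hits / 500)
        assert all(a >= b for a, b in zip(accuracies, accuracies[1:]))
        assert accuracies[0] > 0.9  # short branches are nearly perfectly recoverable
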