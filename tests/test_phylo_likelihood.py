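import dendropy
import numpy as np
import pytest

from conftest import random_sequence
from lineakit.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloError,
    T92Model,
    T92Params,
    build_distance_matrix,
    clade_label_report,
    fit_tree,
    nj_tree,
    optimize_branch_lengths,
    select_topology,
    simulate_alignment,
    t92_distance,
    t92_log_likelihood,
)
from phylo_oracles import (
    all_unrooted_topologies,
    assign_random_branch_lengths,
    brute_force_loglik,
    path_length_matrix,
)


def star_tree(names, lengths=0.0):
    tns = dendropy.TaxonNamespace(names)
    root = dendropy.Node()
    for n in names:
        node = dendropy.Node(taxon=tns.get_taxon(n))
        root.add_child(node)
        node.edge.length = lengths
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


class TestT92Model:
    def test_transition_matrix_rows_sum_to_one(self):
        model = T92Model(T92Params(theta=0.3, kappa=5.0))
        for t in (0.0, 0.01, 0.5, 3.0):
            p = model.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(p >= 0)

    def test_stationary_distribution_preserved(self):
        params = T92Params(theta=0.3, kappa=5.0)
        model = T92Model(params)
        assert np.allclose(params.pi @ model.transition_matrix(2.0), params.pi)

    def test_unit_expected_rate(self):
        model = T92Model(T92Params(theta=0.42, kappa=3.3))
        assert -float(model.params.pi @ np.diag(model.Q)) == pytest.approx(1.0)

    def test_rejects_bad_parameters(self):
        with pytest.raises(PhyloError):
            T92Params(theta=0.0)
        with pytest.raises(PhyloError):
            T92Params(kappa=-1.0)


class TestPruningLikelihood:
    def test_all_missing_column_contributes_zero(self):
        tree = star_tree(["a", "b", "c"], 0.1)
        aln = Alignment(["a", "b", "c"], ["N", "-", "N"])
        assert t92_log_likelihood(tree, aln, T92Params(0.4, 4.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("base,state", [("A", 0), ("C", 1), ("G", 2), ("T", 3)])
    def test_zero_length_star_identical_column(self, base, state):
        tree = star_tree(["a", "b", "c"], 0.0)
        aln = Alignment(["a", "b", "c"], [base] * 3)
        params = T92Params(0.37, 2.5)
        assert t92_log_likelihood(tree, aln, params) == pytest.approx(
            np.log(params.pi[state]), abs=1e-12
        )

    def test_equals_brute_force_enumeration(self, rng):
        """Pruning == explicit summation over internal states, 4 and 5 taxa."""
        params = T92Params(theta=0.45, kappa=3.0)
        for n_taxa in (4, 5):
            taxa = [f"t{i}" for i in range(n_taxa)]
            for topo in all_unrooted_topologies(taxa)[:3]:
                tree = assign_random_branch_lengths(topo, rng)
                seqs = [random_sequence(rng, 8, missing=0.15) for _ in taxa]
                aln = Alignment(taxa, seqs)
                assert t92_log_likelihood(tree, aln, params) == pytest.approx(
                    brute_force_loglik(tree, taxa, seqs, params), abs=1e-9
                )

    def test_taxon_mismatch_rejected(self):
        tree = star_tree(["a", "b", "c"])
        aln = Alignment(["a", "b", "x"], ["A", "A", "A"])
        with pytest.raises(PhyloError):
            t92_log_likelihood(tree, aln, T92Params())


class TestBranchOptimization:
    def _simulated_case(self, rng, n_sites=2000):
        taxa = [f"t{i}" for i in range(4)]
        tree = all_unrooted_topologies(taxa)[0]
        assign_random_branch_lengths(tree, rng, 0.05, 0.2)
        params = T92Params(theta=0.45, kappa=4.0)
        aln = simulate_alignment(tree, params, n_sites, rng)
        aln = Alignment(taxa, [dict(zip(aln.ids, aln.seqs))[t] for t in taxa])
        return tree, aln, params

    def test_loglik_never_decreases(self, rng):
        tree, aln, params = self._simulated_case(rng, 400)
        before = t92_log_likelihood(tree, aln, params)
        optimize_branch_lengths(tree, aln, params, max_sweeps=3)
        after = t92_log_likelihood(tree, aln, params)
        assert after >= before - 1e-9

    def test_fixed_point_of_optimum(self, rng):
        tree, aln, params = self._simulated_case(rng, 400)
        optimize_branch_lengths(tree, aln, params)
        lengths1 = [n.edge.length for n in tree.preorder_node_iter() if n.parent_node]
        optimize_branch_lengths(tree, aln, params, max_sweeps=1)
        lengths2 = [n.edge.length for n in tree.preorder_node_iter() if n.parent_node]
        assert np.allclose(lengths1, lengths2, atol=1e-4)

    def test_two_taxon_ml_length_matches_analytic_distance(self, rng):
        """With kappa free, the ML branch length of a two-leaf tree equals the
        closed-form T92 pairwise distance."""
        params = T92Params(theta=0.45, kappa=4.0)
        tns = dendropy.TaxonNamespace(["a", "b"])
        root = dendropy.Node()
        for name, ln in (("a", 0.06), ("b", 0.06)):
            node = dendropy.Node(taxon=tns.get_taxon(name))
            root.add_child(node)
            node.edge.length = ln
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        aln = simulate_alignment(tree, params, 60000, rng)
        theta = 0.45
        analytic = t92_distance(aln.seqs[0], aln.seqs[1], theta)
        fit = fit_tree(tree, aln, theta=theta, kappa=4.0, optimize_kappa=True)
        total = sum(
            n.edge.length for n in fit.tree.preorder_node_iter() if n.parent_node
        )
        assert total == pytest.approx(analytic, abs=1e-3)


class TestTopologySelection:
    def test_single_candidate_returned(self, rng):
        taxa = [f"t{i}" for i in range(4)]
        tree = assign_random_branch_lengths(all_unrooted_topologies(taxa)[0], rng)
        aln = simulate_alignment(tree, T92Params(0.45, 4.0), 300, rng)
        fit = select_topology([tree], aln, theta=0.45, optimize_kappa=False)
        assert fit.tree is tree

    def test_score_is_loglik_of_returned_tree(self, rng):
        taxa = [f"t{i}" for i in range(4)]
        trees = [
            assign_random_branch_lengths(t, rng)
            for t in all_unrooted_topologies(taxa)
        ]
        aln = simulate_alignment(trees[0], T92Params(0.45, 4.0), 300, rng)
        fit = select_topology(trees, aln, theta=0.45, optimize_kappa=False)
        assert fit.loglik == pytest.approx(
            t92_log_likelihood(fit.tree, aln, fit.params), abs=1e-9
        )

    def test_generating_topology_beats_random_swap(self, rng):
        """With a long internal branch the true topology wins the contest."""
        taxa = ["a", "b", "c", "d"]
        topologies = all_unrooted_topologies(taxa)
        true = topologies[0]
        for node in true.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.05 if node.is_leaf() else 0.5
        params = T92Params(theta=0.45, kappa=4.0)
        aln = simulate_alignment(true, params, 2000, rng)
        wrong = assign_random_branch_lengths(topologies[1], rng)
        fits = [
            select_topology([cand], aln, theta=0.45, optimize_kappa=False)
            for cand in (true, wrong)
        ]
        assert fits[0].loglik > fits[1].loglik

    def test_empty_candidates_rejected(self, rng):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        with pytest.raises(PhyloError):
            select_topology([], aln)


class TestParameterRecovery:
    def test_pairwise_distances_recover_path_lengths(self, rng):
        """T92 simulation on a fixed 6-taxon tree (theta=0.4, kappa=4, 5000
        sites): distance estimates within 10% of true path lengths <= 0.3."""
        taxa = [f"t{i}" for i in range(6)]
        tree = all_unrooted_topologies(taxa)[7]
        assign_random_branch_lengths(tree, rng, 0.02, 0.08)
        params = T92Params(theta=0.4, kappa=4.0)
        aln = simulate_alignment(tree, params, 5000, rng)
        order = aln.ids
        truth = path_length_matrix(tree, order)
        dm = build_distance_matrix(aln, theta=0.4)
        for i in range(6):
            for j in range(i + 1, 6):
                if truth[i, j] <= 0.3:
                    assert dm.matrix[i, j] == pytest.approx(
                        truth[i, j], rel=0.10
                    )


class TestCladeReport:
    def _labelled_tree(self):
        newick = "((q1:0.01,a1:0.01):0.1,(a2:0.01,a3:0.01):0.1,(b1:0.01,(b2:0.01,b3:0.01):0.05):0.2);"
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_sister_label_called(self):
        tree = self._labelled_tree()
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        report = clade_label_report(tree, labels, ["q1"])
        assert report.loc[0, "call"] == "A"
        assert report.loc[0, "clade_size"] == 1

    def test_balanced_membership_is_mixed(self):
        newick = "((q1:0.1,(a1:0.1,b1:0.1):0.1):0.1,a2:0.1,b2:0.1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        report = clade_label_report(tree, labels, ["q1"])
        assert report.loc[0, "call"] == "mixed"

    def test_sibling_queries_are_not_evidence(self):
        newick = "((q1:0.01,q2:0.01):0.1,(a1:0.01,a2:0.01):0.1,b1:0.3);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        report = clade_label_report(tree, labels, ["q1", "q2"])
        assert list(report["call"]) == ["A", "A"]

    def test_missing_query_rejected(self):
        tree = self._labelled_tree()
        with pytest.raises(PhyloError):
            clade_label_report(tree, {}, ["nope"])
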