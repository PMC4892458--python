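import numpy as np
import pytest

import phylosoc as ps
from phylosoc.trees import NewickParseError, NotUltrametricError


class TestNewickIO:
    def test_worked_tree_parses(self, worked_tree):
        assert sorted(ps.tip_labels(worked_tree)) == ["a", "b", "c"]
        labels, d = ps.path_length_matrix(worked_tree)
        i = {l: k for k, l in enumerate(labels)}
        assert d[i["a"], i["b"]] == pytest.approx(2.0)
        assert d[i["a"], i["c"]] == pytest.approx(4.0)

    def test_single_tip_tree(self):
        t = ps.parse_newick("(a:1);")
        assert ps.tip_labels(t) == ["a"]

    def test_parse_error(self):
        with pytest.raises(NewickParseError):
            ps.parse_newick("((a:1,b:1:1,c:2);")

    def test_round_trip_preserves_path_lengths(self, yule_tree_50):
        labels1, d1 = ps.path_length_matrix(yule_tree_50)
        again = ps.parse_newick(ps.write_newick(yule_tree_50))
        labels2, d2 = ps.path_length_matrix(again)
        assert labels1 == labels2
        np.testing.assert_allclose(d1, d2, rtol=1e-10)


class TestPrune:
    def test_path_length_preserved(self, worked_tree):
        pruned = ps.prune_to_taxa(worked_tree, ["a", "b"])
        labels, d = ps.path_length_matrix(pruned)
        assert sorted(labels) == ["a", "b"]
        assert d[0, 1] == pytest.approx(2.0)

    def test_prune_to_all_is_identity(self, yule_tree_50):
        pruned = ps.prune_to_taxa(yule_tree_50, ps.tip_labels(yule_tree_50))
        _, d1 = ps.path_length_matrix(yule_tree_50)
        _, d2 = ps.path_length_matrix(pruned)
        np.testing.assert_allclose(d1, d2, rtol=1e-10)

    def test_prune_random_subset_preserves_distances(self, yule_tree_50):
        labels = ps.tip_labels(yule_tree_50)
        keep = labels[::3]
        pruned = ps.prune_to_taxa(yule_tree_50, keep)
        l1, d1 = ps.path_length_matrix(yule_tree_50)
        l2, d2 = ps.path_length_matrix(pruned)
        i1 = {l: k for k, l in enumerate(l1)}
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                assert d2[l2.index(keep[a]), l2.index(keep[b])] == pytest.approx(
                    d1[i1[keep[a]], i1[keep[b]]], rel=1e-9
                )

    def test_missing_label_listed(self, worked_tree):
        with pytest.raises(KeyError, match="zz"):
            ps.prune_to_taxa(worked_tree, ["a", "zz"])


class TestUltrametric:
    def test_worked_tree_is_ultrametric(self, worked_tree):
        ok, dev = ps.is_ultrametric(worked_tree)
        assert ok and dev == 0.0

    def test_phylogram_is_not(self):
        ok, dev = ps.is_ultrametric(ps.parse_newick("((a:1,b:3):1,c:2);"))
        assert not ok and dev > 0.5

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            ps.is_ultrametric(ps.parse_newick("(a:0,b:0);"))


class TestGraftPolytomy:
    def test_depth_bookkeeping(self, worked_tree):
        g = ps.graft_polytomy(worked_tree, "a", ["x"], 0.5)
        labels, d = ps.path_length_matrix(g)
        i = {l: k for k, l in enumerate(labels)}
        assert d[i["a"], i["x"]] == pytest.approx(1.0)  # sisters joined 0.5 from tips
        assert d[i["a"], i["b"]] == pytest.approx(2.0)
        ok, _ = ps.is_ultrametric(g)
        assert ok

    def test_zero_pendant_multifurcation(self, worked_tree):
        g = ps.graft_polytomy(worked_tree, "a", ["x", "y"], 0.0)
        labels, d = ps.path_length_matrix(g)
        i = {l: k for k, l in enumerate(labels)}
        assert d[i["a"], i["x"]] == 0.0
        assert ps.is_ultrametric(g)[0]

    def test_graft_then_prune_recovers_original(self, yule_tree_50):
        labels = ps.tip_labels(yule_tree_50)
        stem = min(
            l.edge.length for l in yule_tree_50.leaf_node_iter()
            if l.taxon.label == labels[0]
        )
        g = ps.graft_polytomy(
            yule_tree_50, labels[0], ["n1", "n2", "n3"], stem / 2
        )
        back = ps.prune_to_taxa(g, labels)
        _, d1 = ps.path_length_matrix(yule_tree_50)
        _, d2 = ps.path_length_matrix(back)
        np.testing.assert_allclose(d1, d2, rtol=1e-9)

    def test_errors(self, worked_tree):
        with pytest.raises(ValueError, match="exceeds"):
            ps.graft_polytomy(worked_tree, "a", ["x"], 5.0)
        with pytest.raises(ValueError, match="already present"):
            ps.graft_polytomy(worked_tree, "a", ["b"], 0.5)


class TestCongenericDistance:
    def test_single_pair(self, worked_tree):
        d = ps.average_congeneric_distance(worked_tree, {"a": "G", "b": "G"})
        assert d.mean == pytest.approx(2.0)
        assert d.n_pairs == 1

    def test_mean_min_max_two_pairs(self):
        t = ps.parse_newick("((a:0.1,b:0.1):1,(c:0.3,d:0.3):0.8);")
        d = ps.average_congeneric_distance(t, {"a": "G1", "b": "G1", "c": "G2", "d": "G2"})
        assert d.mean == pytest.approx((0.2 + 0.6) / 2)
        assert d.min == pytest.approx(0.2)
        assert d.max == pytest.approx(0.6)

    def test_brute_force_oracle(self, yule_tree_50):
        labels = ps.tip_labels(yule_tree_50)
        genus_map = {lab: f"g{i % 7}" for i, lab in enumerate(labels)}
        got = ps.average_congeneric_distance(yule_tree_50, genus_map)
        ls, d = ps.path_length_matrix(yule_tree_50)
        i = {l: k for k, l in enumerate(ls)}
        brute = [
            d[i[x], i[y]]
            for ai, x in enumerate(labels)
            for y in labels[ai + 1:]
            if genus_map[x] == genus_map[y]
        ]
        assert got.mean == pytest.approx(np.mean(brute), rel=1e-12)
        assert got.n_pairs == len(brute)

    def test_no_pairs_errors(self, worked_tree):
        with pytest.raises(ValueError):
            ps.average_congeneric_distance(worked_tree, {"a": "G1", "b": "G2"})


class TestNPRS:
    def test_clock_like_input_recovered(self, worked_tree):
        out = ps.nprs_ultrametricize(worked_tree, root_age=2.0)
        assert out.nprs_penalty < 1e-8
        _, d1 = ps.path_length_matrix(worked_tree)
        _, d2 = ps.path_length_matrix(out)
        np.testing.assert_allclose(d1, d2, atol=1e-4)

    def test_two_tip_closed_form(self):
        # no free node ages: rates are 1 and 3, penalty fixed at
        # (1-2)^2 + (3-2)^2 = 2 for any root age
        out = ps.nprs_ultrametricize(ps.parse_newick("(a:1,b:3);"), root_age=1.0)
        assert out.nprs_penalty == pytest.approx(2.0)
        assert ps.is_ultrametric(out)[0]

    def test_output_always_ultrametric(self):
        rng = np.random.default_rng(3)
        t = ps.simulate_yule_tree(20, seed=9)
        # perturb branch lengths into a relaxed-clock phylogram
        for node in t.preorder_node_iter():
            if node.edge.length:
                node.edge.length *= rng.lognormal(0.0, 0.5)
        out = ps.nprs_ultrametricize(t, root_age=1.0)
        ok, dev = ps.is_ultrametric(out, rel_tol=1e-6)
        assert ok, dev

    def test_scale_equivariance(self):
        t1 = ps.simulate_yule_tree(15, seed=4)
        rng = np.random.default_rng(5)
        for node in t1.preorder_node_iter():
            if node.edge.length:
                node.edge.length *= rng.lognormal(0.0, 0.3)
        t2 = ps.parse_newick(ps.write_newick(t1))
        for node in t2.preorder_node_iter():
            if node.edge.length:
                node.edge.length *= 7.5
        o1 = ps.nprs_ultrametricize(t1, root_age=1.0)
        o2 = ps.nprs_ultrametricize(t2, root_age=1.0)
        _, d1 = ps.path_length_matrix(o1)
        _, d2 = ps.path_length_matrix(o2)
        np.testing.assert_allclose(d1, d2, atol=1e-5)

    def test_recovers_true_ages_on_relaxed_clock(self):
        # mild rate heterogeneity: smoothed ages track the true ones
        true = ps.simulate_yule_tree(50, seed=21)
        depth = ps.trees.tree_depth(true)
        rng = np.random.default_rng(22)
        noisy = ps.parse_newick(ps.write_newick(true))
        for node in noisy.preorder_node_iter():
            if node.edge.length:
                node.edge.length *= rng.lognormal(0.0, 0.3)
        out = ps.nprs_ultrametricize(noisy, root_age=depth)
        from phylosoc.trees import _node_depths

        def internal_ages(tree, total):
            ages = {}
            nd = _node_depths(tree)
            for i, node in enumerate(tree.preorder_node_iter()):
                if not node.is_leaf():
                    ages[i] = total - nd[node]
            return np.array([ages[k] for k in sorted(ages)])

        a_true = internal_ages(true, depth)
        a_est = internal_ages(out, depth)
        from scipy.stats import spearmanr

        rho = spearmanr(a_true, a_est).statistic
        assert rho > 0.9


class TestCorrelationFromTree:
    def test_worked_example(self, worked_tree):
        C = ps.correlation_from_tree(worked_tree)
        df = C.to_frame()
        assert df.loc["a", "b"] == pytest.approx(0.5)
        assert df.loc["a", "c"] == 0.0
        assert df.loc["b", "c"] == 0.0
        np.testing.assert_array_equal(np.diag(C.values), 1.0)

    def test_star_tree_identity(self):
        star = ps.parse_newick("(a:1,b:1,c:1,d:1);")
        C = ps.correlation_from_tree(star)
        np.testing.assert_allclose(C.values, np.eye(4))

    def test_two_tip_identity(self):
        C = ps.correlation_from_tree(ps.parse_newick("(a:1,b:1);"))
        np.testing.assert_allclose(C.values, np.eye(2))

    def test_yule_tree_is_psd(self, yule_tree_50):
        C = ps.correlation_from_tree(yule_tree_50)
        assert C.min_eigenvalue() >= -1e-10

    def test_non_ultrametric_rejected(self):
        with pytest.raises(NotUltrametricError, match="nprs"):
            ps.correlation_from_tree(ps.parse_newick("((a:1,b:3):1,c:2);"))
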