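"""Graphical lasso path, StARS, bootstrap rule, network statistics."""

import networkx as nx
import numpy as np
import pytest

from gutsig import network as net
from gutsig import synthetic
from oracles import evc_dense


def draw_gaussian(omega, n, seed=0):
    sigma = np.linalg.inv(omega)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(len(omega)), sigma, size=n)


class TestGlassoPath:
    def test_huge_penalty_gives_empty_graph(self):
        X = np.random.default_rng(0).normal(size=(100, 5))
        omega = net.glasso_path(X, [100.0])[0]
        assert net.support_matrix(omega).sum() == 0

    def test_independent_columns_stay_unconnected(self):
        X = np.random.default_rng(1).normal(size=(400, 6))
        lam_max = net.lambda_path(np.cov(X, rowvar=False))[0]
        omega = net.glasso_path(X, [lam_max])[0]
        assert net.support_matrix(omega).sum() == 0

    def test_chain_truth_recovered_at_small_penalty(self):
        omega_true, _, _ = synthetic.sample_precision_matrix(
            3, 0.5, seed=0, support={(0, 1), (1, 2)}
        )
        X = draw_gaussian(omega_true, 2000, seed=2)
        omega = net.glasso_path(X, [0.02])[0]
        sup = net.support_matrix(omega)
        assert sup[0, 1] and sup[1, 2] and not sup[0, 2]

    def test_edge_count_monotone_in_penalty(self):
        omega_true, _, _ = synthetic.sample_precision_matrix(10, 0.3, seed=1)
        X = draw_gaussian(omega_true, 300, seed=3)
        lams = net.lambda_path(np.cov(X, rowvar=False), n_lambdas=12)
        counts = [net.support_matrix(o).sum() for o in net.glasso_path(X, lams)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_small_penalty_matches_inverse_covariance_support(self):
        omega_true, _, _ = synthetic.sample_precision_matrix(
            5, 0.4, seed=4, support={(0, 1), (2, 3)}
        )
        X = draw_gaussian(omega_true, 5000, seed=5)
        omega = net.glasso_path(X, [1e-3])[0]
        S_inv = np.linalg.inv(np.cov(X, rowvar=False))
        # entries that are solidly nonzero in S^-1 should be edges
        strong = (np.abs(S_inv) > 0.05) & ~np.eye(5, dtype=bool)
        assert (net.support_matrix(omega) | ~strong).all()


class TestStars:
    def test_degenerate_subsamples_have_zero_instability(self):
        X = np.random.default_rng(0).normal(size=(40, 5))
        sel = net.stars_select(X, subsample_size=40, subsample_count=4, seed=0)
        assert np.allclose(sel["instability"], 0.0)

    def test_beta_zero_selects_a_perfectly_stable_graph(self):
        X = np.random.default_rng(1).normal(size=(60, 5))
        lams = [5.0, 1.0, 0.5, 0.2, 0.1, 0.05, 0.01]
        sel = net.stars_select(X, lambdas=lams, subsample_count=6, beta=0.0, seed=1)
        i = list(sel["lambdas"]).index(sel["lambda_star"])
        assert sel["monotone_instability"][i] == 0.0
        # the selected penalty is the smallest (densest) perfectly stable one
        assert np.all(sel["monotone_instability"][i + 1:] > 0)

    def test_all_unstable_falls_back_to_largest_penalty(self):
        X = np.random.default_rng(2).normal(size=(30, 6))
        with pytest.warns(UserWarning):
            sel = net.stars_select(X, lambdas=[0.02, 0.01], subsample_count=6,
                                   beta=0.0, seed=2)
        assert sel["lambda_star"] == 0.02


class TestBootstrapRule:
    def _omega(self):
        omega = np.eye(3)
        omega[0, 1] = omega[1, 0] = -0.4
        omega[1, 2] = omega[2, 1] = 0.3
        return omega

    @pytest.mark.parametrize("count,kept", [(40, True), (39, False), (50, True)])
    def test_exact_threshold_at_f_times_r(self, count, kept):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1] = counts[1, 0] = count
        counts[1, 2] = counts[2, 1] = 50
        out = net.apply_stability_rule(self._omega(), counts, r=50, f=0.8)
        assert bool(out[0, 1] != 0) == kept
        assert out[1, 2] != 0  # always reproduced
        assert out[0, 0] == 1.0  # diagonal untouched

    def test_f_zero_keeps_everything(self):
        counts = np.zeros((3, 3), dtype=int)
        out = net.apply_stability_rule(self._omega(), counts, r=50, f=0.0)
        np.testing.assert_array_equal(out, self._omega())

    def test_stabilization_never_adds_edges_and_is_monotone_in_f(self):
        omega_true, _, _ = synthetic.sample_precision_matrix(10, 0.2, seed=2)
        X = draw_gaussian(omega_true, 200, seed=6)
        lam = net.lambda_path(np.cov(X, rowvar=False))[10]
        full = net.support_matrix(net.glasso_path(X, [lam])[0])
        edge_sets = []
        for f in (0.0, 0.8, 1.0):
            est = net.bootstrap_stabilize(X, lam, r=20, f=f, seed=7)
            edges = net.build_network(est).edges
            edge_sets.append(edges)
        full_edges = {
            frozenset((est.species[i], est.species[j]))
            for i, j in zip(*np.where(np.triu(full, 1)))
        }
        assert edge_sets[0] <= full_edges
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]


class TestBuildNetwork:
    def test_diagonal_precision_gives_empty_network(self):
        est = net.PrecisionEstimate(["a", "b"], np.eye(2), lam=0.1)
        assert net.build_network(est).graph.number_of_edges() == 0

    def test_negative_precision_entry_is_positive_association(self):
        omega = np.array([[1.0, -0.5], [-0.5, 1.0]])
        g = net.build_network(net.PrecisionEstimate(["a", "b"], omega, 0.1))
        assert g.edge_sign("a", "b") == 1

    def test_chain_degrees(self):
        omega = np.eye(3)
        omega[0, 1] = omega[1, 0] = 0.3
        omega[1, 2] = omega[2, 1] = 0.3
        g = net.build_network(net.PrecisionEstimate(list("abc"), omega, 0.1))
        assert list(g.degree[list("abc")]) == [1, 2, 1]


class TestEigenvectorCentrality:
    def test_star_center_is_most_central(self):
        g = nx.star_graph(4)
        evc = net.eigenvector_centrality(g)
        assert evc[0] == evc.max()

    def test_path_graph_closed_form(self):
        evc = net.eigenvector_centrality(nx.path_graph(3))
        expected = np.array([1.0, np.sqrt(2), 1.0])
        np.testing.assert_allclose(evc.to_numpy(), expected / np.linalg.norm(expected),
                                   atol=1e-10)

    def test_complete_graph_is_uniform(self):
        evc = net.eigenvector_centrality(nx.complete_graph(5))
        np.testing.assert_allclose(evc, 1 / np.sqrt(5), atol=1e-10)

    def test_matches_dense_eigendecomposition(self):
        for seed in range(20):
            g = nx.gnp_random_graph(np.random.default_rng(seed).integers(5, 40),
                                    0.15, seed=seed)
            if g.number_of_edges() == 0:
                continue
            mine = net.eigenvector_centrality(g).to_numpy()
            oracle = evc_dense(nx.to_numpy_array(g))
            np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            net.eigenvector_centrality(nx.Graph())


class TestCompareNetworks:
    def _net(self, edges, nodes=("a", "b", "c", "d")):
        omega = np.eye(len(nodes))
        for i, j in edges:
            omega[i, j] = omega[j, i] = -0.3
        return net.build_network(net.PrecisionEstimate(list(nodes), omega, 0.1))

    def test_identical_networks(self):
        a = self._net([(0, 1), (1, 2)])
        b = self._net([(0, 1), (1, 2)])
        rep = net.compare_networks(a, b, top_k=4)
        assert rep["n_unique"] == {"a": 0, "b": 0}
        assert rep["top_k_overlap"] == 4

    def test_disjoint_edge_sets(self):
        a = self._net([(0, 1)])
        b = self._net([(2, 3)])
        rep = net.compare_networks(a, b)
        assert rep["n_unique"] == {"a": 1, "b": 1} and not rep["shared_edges"]

    def test_exact_edge_difference_reported(self):
        base = [(0, 1), (1, 2)]
        extra = [(0, 2), (0, 3), (1, 3), (2, 3)]
        a = self._net(base + extra)
        b = self._net(base)
        rep = net.compare_networks(a, b)
        assert rep["unique_edges"]["a"] == {frozenset(("abcd"[i], "abcd"[j]))
                                            for i, j in extra}

    def test_da_category_fractions(self):
        a = self._net([(0, 1), (1, 2)])
        b = self._net([(0, 1)])
        rep = net.compare_networks(a, b, da_labels={"a": "elevated"})
        # connected nodes in a: a,b,c -> 1/3 elevated
        assert rep["node_category_fractions"]["a"]["elevated"] == pytest.approx(1 / 3)
        assert rep["unique_edge_elevated_fraction"]["b"] == 0.0
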