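import warnings

import numpy as np
import pytest

from conftest import planted_graph
from morbnet.catalog import NETWORK_NODES
from morbnet.ising import (
    EbicPath,
    EstimatorConfig,
    IsingNetwork,
    assemble_network,
    ebic_value,
    estimate_network,
    estimate_stratified_networks,
    fit_nodewise_lasso,
)
from morbnet.synthetic import sample_ising_exact, sample_ising_gibbs
from oracles import exhaustive_ebic_support


def toy_data(n=2000, seed=0, w=1.5):
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = w
    return sample_ising_exact(W, np.full(4, -1.0), n, seed=seed)


class TestEbic:
    def test_formula_value(self):
        # -2*(-100) + 3*ln(500) + 2*0.25*3*ln(18)
        expected = 200 + 3 * np.log(500) + 1.5 * np.log(18)
        assert ebic_value(-100.0, 3, 500, 18, 0.25) == pytest.approx(expected)
        assert expected == pytest.approx(222.98, abs=0.01)

    def test_full_shrinkage_limit_is_intercept_only(self):
        X = toy_data(seed=1)
        path = fit_nodewise_lasso(X, 0, lambdas=np.array([10.0, 5.0]))
        assert path.n_nonzero[0] == 0
        # EBIC at k=0 is -2 * intercept-only log-likelihood
        y = X[:, 0]
        pbar = y.mean()
        ll0 = len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
        assert path.ebic[0] == pytest.approx(-2 * ll0, rel=1e-9)

    def test_selection_is_argmin_over_grid(self):
        X = toy_data(seed=2)
        path = fit_nodewise_lasso(X, 0)
        assert path.selected == int(np.argmin(path.ebic))

    def test_sparsity_nonincreasing_in_lambda_on_toy(self):
        X = toy_data(seed=3)
        path = fit_nodewise_lasso(X, 1)
        assert np.all(np.diff(path.n_nonzero) >= 0)  # grid is descending


class TestNodewiseLasso:
    def test_matches_exhaustive_all_subsets_search(self):
        X = toy_data(seed=4)
        for node in range(4):
            path = fit_nodewise_lasso(X, node)
            others = [j for j in range(4) if j != node]
            sel = frozenset(others[i] for i in np.flatnonzero(path.selected_coefs))
            assert sel == exhaustive_ebic_support(X, node)

    def test_kkt_conditions_at_path_solutions(self):
        from morbnet._lasso import lasso_logistic_path, make_lambda_grid
        from scipy.special import expit

        rng = np.random.default_rng(5)
        X = (rng.random((400, 6)) < 0.4).astype(float)
        y = X[:, 0]
        Xo = X[:, 1:]
        grid = make_lambda_grid(Xo, y, 30)
        b0s, coefs, _ = lasso_logistic_path(Xo, y, grid, tol=1e-6)
        n = len(y)
        for i in (0, 10, 20, 29):
            beta = coefs[i]
            lam = grid[i]
            prob = expit(b0s[i] + Xo @ beta)
            g = -(Xo.T @ (y - prob)) / n
            zero = beta == 0.0
            if zero.any():
                assert np.all(np.abs(g[zero]) <= lam + 1e-5)
            if (~zero).any():
                assert np.all(np.abs(g[~zero] + lam * np.sign(beta[~zero])) <= 1e-5)

    def test_matches_sklearn_saga_solution(self):
        from morbnet._lasso import fit_lasso_logistic
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(6)
        n = 800
        X = (rng.random((n, 8)) < 0.35).astype(float)
        y = X[:, 0]
        Xo = X[:, 1:]
        lam = 0.01
        b0, beta = fit_lasso_logistic(Xo, y, lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(
                C=1 / (n * lam), l1_ratio=1.0, penalty="elasticnet",
                solver="saga", tol=1e-12, max_iter=100_000,
            ).fit(Xo, y)
        assert np.allclose(beta, clf.coef_[0], atol=1e-6)

    def test_constant_node_rejected(self):
        X = toy_data(seed=7)
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_nodewise_lasso(X, 2)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_nodewise_lasso(np.full((10, 3), 0.5), 0)


def _path_with_selected(node, p, coef_map, intercept=0.0):
    """A single-point EbicPath whose selection carries the given coefficients."""
    coefs = np.zeros((1, p - 1))
    for j, v in coef_map.items():
        coefs[0, j] = v
    return EbicPath(
        node=node, lambdas=np.array([0.1]), intercepts=np.array([intercept]),
        coefs=coefs, loglik=np.array([-10.0]), n=100, gamma=0.25,
        ml_intercepts=np.array([intercept]), ml_coefs=coefs,
    )


class TestAssembleNetwork:
    def test_and_rule_averages_bidirectional_coefficients(self):
        paths = {
            0: _path_with_selected(0, 3, {0: 0.6}),  # 1 in 0's regression
            1: _path_with_selected(1, 3, {0: 0.4}),  # 0 in 1's regression
            2: _path_with_selected(2, 3, {}),
        }
        net = assemble_network(paths, ["a", "b", "c"], rule="and")
        assert net.weights[0, 1] == pytest.approx(0.5)
        assert net.weights[0, 2] == 0.0

    def test_one_directional_edge_depends_on_rule(self):
        paths = {
            0: _path_with_selected(0, 3, {0: 0.6}),
            1: _path_with_selected(1, 3, {}),
            2: _path_with_selected(2, 3, {}),
        }
        net_and = assemble_network(paths, ["a", "b", "c"], rule="and")
        net_or = assemble_network(paths, ["a", "b", "c"], rule="or")
        assert net_and.weights[0, 1] == 0.0
        assert net_or.weights[0, 1] == pytest.approx(0.3)

    def test_inconsistent_node_sets_rejected(self):
        with pytest.raises(ValueError, match="one path per"):
            assemble_network({0: _path_with_selected(0, 3, {})}, ["a", "b", "c"])

    def test_network_invariants_validated(self):
        W = np.zeros((2, 2))
        W[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            IsingNetwork(["a", "b"], W, np.zeros(2), 0.25, 100)


class TestEstimateNetwork:
    def test_planted_graph_recovery_single_replicate(self):
        W, true_pairs = planted_graph(seed=8)
        X = sample_ising_gibbs(W, np.full(10, -1.0), 2000, seed=9)
        net = estimate_network(X, [f"v{i}" for i in range(10)])
        est = {
            (i, j)
            for i in range(10)
            for j in range(i + 1, 10)
            if net.weights[i, j] != 0
        }
        tp = len(true_pairs & est)
        assert tp / len(true_pairs) >= 0.8
        # detected planted edges must carry the planted (positive) sign
        assert all(net.weights[i, j] > 0 for (i, j) in true_pairs & est)

    def test_independent_data_yields_sparse_network(self):
        rng = np.random.default_rng(10)
        X = (rng.random((5000, 6)) < 0.3).astype(float)
        net = estimate_network(X, [f"v{i}" for i in range(6)])
        assert len(net.edge_list()) <= 1  # EBIC selection is conservative

    def test_constant_column_dropped_and_recorded(self):
        X = toy_data(seed=11)
        X[:, 3] = 0.0
        net = estimate_network(X, ["a", "b", "c", "d"])
        assert net.nodes == ["a", "b", "c"]
        assert "d" in net.dropped_nodes

    def test_serialisation_roundtrip(self, tmp_path):
        X = toy_data(seed=12)
        net = estimate_network(X, ["a", "b", "c", "d"])
        net.to_json(tmp_path / "net.json")
        back = IsingNetwork.from_json(tmp_path / "net.json")
        assert back.nodes == net.nodes
        assert np.allclose(back.weights, net.weights)
        net.to_graphml(tmp_path / "net.graphml")
        import networkx as nx

        G = nx.read_graphml(tmp_path / "net.graphml")
        assert set(G.nodes) == set(net.nodes)


class TestStratifiedNetworks:
    def test_five_strata_give_five_networks(self, complete_cohort):
        cfg = EstimatorConfig(n_lambda=30, min_stratum_n=100)
        nets = estimate_stratified_networks(complete_cohort, cfg)
        assert set(nets) == {"female", "male", "50-59", "60-74", "75+"}
        for net in nets.values():
            assert np.allclose(net.weights, net.weights.T)

    def test_identical_strata_give_identical_networks(self, complete_cohort):
        cfg = EstimatorConfig(n_lambda=30)
        X = complete_cohort[list(NETWORK_NODES)].to_numpy(float)[:1500]
        a = estimate_network(X, list(NETWORK_NODES), cfg)
        b = estimate_network(X, list(NETWORK_NODES), cfg)
        assert np.array_equal(a.weights, b.weights)

    def test_small_stratum_skipped_with_warning(self, complete_cohort):
        cfg = EstimatorConfig(n_lambda=30, min_stratum_n=10**6)
        with pytest.warns(UserWarning, match="skipped"):
            nets = estimate_stratified_networks(complete_cohort, cfg)
        assert nets == {}
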