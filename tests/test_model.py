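"""Core model: Laplacian, closed-form propagation, risks, gradients, training."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import cho_solve
from scipy.special import expit

import synprop as sp
from synprop.model import (
    ModelParams,
    _loss_sensitivity,
    _propagation_factor,
    grad_phi,
    grad_theta,
)

from conftest import make_expression, make_labels, make_network, random_network


class TestNormalizedLaplacian:
    def test_edgeless_graph_gives_identity(self):
        L = sp.normalized_laplacian(make_network(np.zeros((3, 3))))
        np.testing.assert_allclose(L.matrix, np.eye(3))

    def test_single_edge_normalization_cancels_weight(self):
        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        L = sp.normalized_laplacian(make_network(W))
        np.testing.assert_allclose(L.matrix, [[1, -1], [-1, 1]], atol=1e-12)

    def test_spectrum_in_0_2_with_zero_per_component(self, rng):
        net = random_network(6, 0.6, rng)
        L = sp.normalized_laplacian(net)
        eig = np.linalg.eigvalsh(L.matrix)
        assert eig.min() > -1e-10 and eig.max() < 2 + 1e-10
        # count connected components of the graph; each contributes a 0 eigenvalue
        import networkx as nx

        g = nx.from_numpy_array(net.weights)
        n_comp = nx.number_connected_components(g)
        assert np.sum(np.abs(eig) < 1e-8) == n_comp

    def test_rejects_invalid_network(self):
        with pytest.raises(ValueError, match="symmetric"):
            sp.PPINetwork(weights=np.array([[0, 0.5], [0.2, 0]]), protein_ids=["a", "b"])
        with pytest.raises(ValueError, match="negative"):
            sp.PPINetwork(weights=np.array([[0, -0.5], [-0.5, 0]]), protein_ids=["a", "b"])


class TestPropagate:
    def test_edgeless_diagonal_shrinkage_exact(self, rng):
        X = make_expression(rng.uniform(size=(4, 6)))
        phi = rng.uniform(0.2, 3.0, 4)
        L = sp.normalized_laplacian(make_network(np.zeros((4, 4))))
        Z = sp.propagate(X, L, phi)
        np.testing.assert_allclose(
            Z.values, phi[:, None] * X.values / (1.0 + phi[:, None]), rtol=1e-12
        )

    def test_two_node_single_edge_solve(self):
        X = make_expression([[1.0], [0.0]])
        L = sp.normalized_laplacian(make_network([[0, 0.7], [0.7, 0]]))
        Z = sp.propagate(X, L, np.ones(2))
        # (Phi + L) = [[2,-1],[-1,2]]; solving against (1, 0) gives (2/3, 1/3)
        np.testing.assert_allclose(Z.values[:, 0], [2 / 3, 1 / 3], rtol=1e-12)

    def test_large_phi_recovers_independent_effects(self, rng):
        X = make_expression(rng.uniform(size=(5, 7)))
        net = random_network(5, 0.7, rng)
        L = sp.normalized_laplacian(net)
        Z = sp.propagate(X, L, np.full(5, 1e6))
        assert np.max(np.abs(Z.values - X.values)) <= 1e-4

    def test_closed_form_matches_fixed_point_iteration(self, rng):
        for d in (5, 20, 50):
            X = make_expression(rng.uniform(size=(d, 4)))
            net = random_network(d, 0.3, rng)
            L = sp.normalized_laplacian(net)
            phi = rng.uniform(0.2, 2.0, d)
            Z_closed = sp.propagate(X, L, phi).values
            Z_iter = sp.iterative_propagate(X, L, phi, tol=1e-13).values
            assert np.max(np.abs(Z_closed - Z_iter)) < 1e-8

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity_in_expression(self, seed, a, b):
        rng = np.random.default_rng(seed)
        d = 6
        X1, X2 = rng.uniform(size=(d, 3)), rng.uniform(size=(d, 3))
        net = random_network(d, 0.5, rng)
        L = sp.normalized_laplacian(net)
        phi = rng.uniform(0.3, 2.0, d)
        lhs = sp.propagate(make_expression(a * X1 + b * X2), L, phi).values
        rhs = a * sp.propagate(make_expression(X1), L, phi).values + b * sp.propagate(
            make_expression(X2), L, phi
        ).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_phi_plus_laplacian_is_positive_definite(self, rng):
        for _ in range(5):
            d = 7
            net = random_network(d, 0.5, rng)
            L = sp.normalized_laplacian(net)
            phi = rng.uniform(1e-4, 3.0, d)
            eig_min = np.linalg.eigvalsh(L.matrix + np.diag(phi)).min()
            assert eig_min > 0

    def test_per_sample_independence(self, rng):
        X = rng.uniform(size=(5, 8))
        net = random_network(5, 0.5, rng)
        L = sp.normalized_laplacian(net)
        phi = rng.uniform(0.3, 2.0, 5)
        Z_full = sp.propagate(make_expression(X), L, phi).values
        Z_col3 = sp.propagate(make_expression(X[:, [3]]), L, phi).values
        np.testing.assert_allclose(Z_full[:, [3]], Z_col3, rtol=1e-12)

    def test_nonpositive_phi_rejected(self, rng):
        X = make_expression(rng.uniform(size=(3, 2)))
        L = sp.normalized_laplacian(make_network(np.zeros((3, 3))))
        with pytest.raises(ValueError, match="strictly positive"):
            sp.propagate(X, L, np.array([1.0, 0.0, 1.0]))


class TestRiskAndLosses:
    def test_zero_theta_gives_half(self, rng):
        Z = rng.normal(size=(4, 9))
        np.testing.assert_allclose(sp.estimate_risk(Z, np.zeros(4)), 0.5)

    def test_logistic_at_ln3_is_three_quarters(self):
        Z = np.array([[np.log(3.0)]])
        np.testing.assert_allclose(sp.estimate_risk(Z, np.ones(1)), 0.75)

    def test_negating_theta_mirrors_scores(self, rng):
        Z = rng.normal(size=(5, 6))
        theta = rng.normal(size=5)
        np.testing.assert_allclose(
            sp.estimate_risk(Z, -theta), 1.0 - sp.estimate_risk(Z, theta), rtol=1e-9
        )

    def test_bce_uninformative_prediction_is_ln2(self):
        assert sp.bce_loss(np.array([0.5, 0.5]), np.array([1, 0])) == pytest.approx(
            np.log(2.0)
        )

    def test_bce_frozen_scalar_value(self):
        # -(1/2)[ln 0.9 + ln 0.9] = -ln 0.9
        loss = sp.bce_loss(np.array([0.9, 0.1]), np.array([1, 0]))
        assert loss == pytest.approx(-np.log(0.9), rel=1e-12)

    def test_bce_nonnegative_and_vanishes_at_truth(self, rng):
        y = rng.integers(0, 2, 20)
        p = rng.uniform(0.01, 0.99, 20)
        assert sp.bce_loss(p, y) >= 0
        assert sp.bce_loss(np.clip(y.astype(float), 1e-12, 1 - 1e-12), y) < 1e-10

    def test_bce_rejects_nonbinary_labels(self):
        with pytest.raises(ValueError, match="binary"):
            sp.bce_loss(np.array([0.5]), np.array([2]))

    def test_objective_uninformative_start_is_tasks_times_ln2(self, rng):
        X = make_expression(rng.uniform(size=(5, 8)))
        net = random_network(5, 0.5, rng)
        L = sp.normalized_laplacian(net)
        labels = make_labels({b: rng.integers(0, 2, 8) for b in "ABCD"}, 8)
        params = ModelParams(phi=np.ones(5), theta={b: np.zeros(5) for b in "ABCD"}, delta=0.0)
        assert sp.total_objective(params, X, L, labels) == pytest.approx(4 * np.log(2.0))

    def test_objective_regularizer_contribution(self, rng):
        # delta ||phi||^2 alone: phi = (1,1), delta = 0.5 adds exactly 1.0
        X = make_expression(rng.uniform(size=(2, 4)))
        L = sp.normalized_laplacian(make_network(np.zeros((2, 2))))
        labels = make_labels({"A": rng.integers(0, 2, 4)}, 4)
        base = ModelParams(phi=np.ones(2), theta={"A": np.zeros(2)}, delta=0.0)
        reg = ModelParams(phi=np.ones(2), theta={"A": np.zeros(2)}, delta=0.5)
        diff = sp.total_objective(reg, X, L, labels) - sp.total_objective(base, X, L, labels)
        assert diff == pytest.approx(1.0)

    def test_objective_matches_independent_recomputation(self, rng):
        d, n = 6, 9
        X = make_expression(rng.uniform(size=(d, n)))
        net = random_network(d, 0.5, rng)
        L = sp.normalized_laplacian(net)
        labels = make_labels({b: rng.integers(0, 2, n) for b in ("A", "B")}, n)
        phi = rng.uniform(0.3, 2.0, d)
        theta = {b: rng.normal(size=d) for b in ("A", "B")}
        delta = 0.01
        params = ModelParams(phi=phi, theta=theta, delta=delta)
        # brute force from scratch with plain numpy
        A = np.diag(phi) + L.matrix
        Z = np.linalg.solve(A, phi[:, None] * X.values)
        expected = delta * (phi @ phi)
        for b in ("A", "B"):
            p = 1.0 / (1.0 + np.exp(-(theta[b] @ Z)))
            y = labels.labels[b]
            expected += -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            expected += delta * (theta[b] @ theta[b])
        assert sp.total_objective(params, X, L, labels) == pytest.approx(expected, rel=1e-10)


def _finite_diff(obj, params, kind, name, i, h=1e-6):
    import copy

    up = copy.deepcopy(params)
    dn = copy.deepcopy(params)
    if kind == "phi":
        up.phi[i] += h
        dn.phi[i] -= h
    else:
        up.theta[name][i] += h
        dn.theta[name][i] -= h
    return (obj(up) - obj(dn)) / (2 * h)


class TestGradients:
    def test_grad_theta_reduces_to_regularizer_when_z_zero(self):
        g = grad_theta(np.zeros((3, 5)), np.full(5, 0.5), np.zeros(5), np.ones(3), 0.2)
        np.testing.assert_allclose(g, 0.4 * np.ones(3))

    def test_grad_theta_closed_form_at_uninformative_scores(self, rng):
        Z = rng.uniform(size=(4, 10))
        y = rng.integers(0, 2, 10).astype(float)
        g = grad_theta(Z, np.full(10, 0.5), y, np.zeros(4), 0.0)
        np.testing.assert_allclose(g, Z @ (0.5 - y) / 10, rtol=1e-12)

    def test_grad_phi_reduces_to_regularizer_without_data_signal(self, rng):
        d = 5
        X = make_expression(rng.uniform(size=(d, 6)))
        net = random_network(d, 0.5, rng)
        L = sp.normalized_laplacian(net)
        phi = rng.uniform(0.5, 2.0, d)
        fac = _propagation_factor(L, phi)
        Z = cho_solve(fac, phi[:, None] * X.values)
        G = np.zeros((d, 6))  # all theta zero
        g = grad_phi(phi, X.values, Z, G, fac, 0.3)
        np.testing.assert_allclose(g, 0.6 * phi, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_both_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        d, n = 8, 12
        X = make_expression(rng.uniform(size=(d, n)))
        net = random_network(d, 0.4, rng)
        L = sp.normalized_laplacian(net)
        labels = make_labels({b: rng.integers(0, 2, n) for b in ("A", "B")}, n)
        phi = rng.uniform(0.5, 2.0, d)
        theta = {b: rng.normal(size=d) for b in ("A", "B")}
        delta = 0.01
        params = ModelParams(
            phi=phi.copy(), theta={k: v.copy() for k, v in theta.items()}, delta=delta
        )
        fac = _propagation_factor(L, phi)
        Z = cho_solve(fac, phi[:, None] * X.values)
        P = {b: np.clip(expit(theta[b] @ Z), 1e-12, 1 - 1e-12) for b in theta}
        Y = {b: labels.labels[b].astype(float) for b in theta}
        G = _loss_sensitivity(theta, P, Y, n)
        g_phi = grad_phi(phi, X.values, Z, G, fac, delta)
        g_theta = grad_theta(Z, P["A"], Y["A"], theta["A"], delta)

        def obj(p):
            return sp.total_objective(p, X, L, labels)

        for i in range(d):
            fd = _finite_diff(obj, params, "phi", None, i)
            assert abs(fd - g_phi[i]) <= 1e-5 * max(abs(fd), 1e-6)
            fd = _finite_diff(obj, params, "theta", "A", i)
            assert abs(fd - g_theta[i]) <= 1e-5 * max(abs(fd), 1e-6)

    def test_grad_phi_edgeless_scalar_calculus(self, rng):
        # with L = I: Z_ij = phi_i x_ij / (1 + phi_i), dZ_ij/dphi_i = x_ij/(1+phi_i)^2
        d, n = 4, 7
        X = rng.uniform(size=(d, n))
        L = sp.normalized_laplacian(make_network(np.zeros((d, d))))
        phi = rng.uniform(0.5, 2.0, d)
        theta = rng.normal(size=d)
        y = rng.integers(0, 2, n).astype(float)
        fac = _propagation_factor(L, phi)
        Z = cho_solve(fac, phi[:, None] * X)
        P = np.clip(expit(theta @ Z), 1e-12, 1 - 1e-12)
        G = _loss_sensitivity({"A": theta}, {"A": P}, {"A": y}, n)
        g = grad_phi(phi, X, Z, G, fac, 0.0)
        # A = diag(1 + phi), so row_i(A^{-1} G) = G_i / (1 + phi_i)
        expected = np.array(
            [np.sum(G[i] / (1.0 + phi[i]) * (X[i] - Z[i])) for i in range(d)]
        )
        np.testing.assert_allclose(g, expected, rtol=1e-10)


class TestFitAndPredict:
    @pytest.fixture
    def small_data(self):
        data = sp.make_dataset(sp.SyntheticSpec(d=12, n=120, seed=4, theta_scale=1.5))
        return data

    def test_strong_regularization_shrinks_theta_monotonically(self, small_data):
        cfg = sp.TrainConfig(
            max_epochs=60, optimizer="plain-gd", eta=1e-4, delta=1e3, tol=0.0,
            init_scale=0.5, seed=1,
        )
        d = small_data.X.n_proteins
        # track ||theta|| across manual refits of increasing length
        norms = []
        for epochs in (5, 20, 60):
            res = sp.fit(
                small_data.X, small_data.network, small_data.labels,
                sp.TrainConfig(max_epochs=epochs, optimizer="plain-gd", eta=1e-4,
                               delta=1e3, tol=0.0, init_scale=0.5, seed=1),
            )
            norms.append(
                sum(np.linalg.norm(v) for v in res.params.theta.values())
            )
        assert norms[0] > norms[1] > norms[2]

    def test_plain_gd_loss_trace_mostly_nonincreasing(self, small_data):
        cfg = sp.TrainConfig(max_epochs=300, optimizer="plain-gd", eta=0.05, tol=0.0)
        res = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        diffs = np.diff(res.loss_trace)
        assert (diffs <= 1e-12).mean() >= 0.95

    def test_initial_loss_is_tasks_times_ln2_at_zero_theta(self, small_data):
        cfg = sp.TrainConfig(max_epochs=1, delta=0.0)
        res = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        n_tasks = len(small_data.labels.biomarkers)
        assert res.loss_trace[0] == pytest.approx(n_tasks * np.log(2.0))

    def test_fit_deterministic_given_config(self, small_data):
        cfg = sp.TrainConfig(max_epochs=30, seed=7, init_scale=0.1)
        r1 = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        r2 = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        np.testing.assert_array_equal(r1.params.phi, r2.params.phi)
        np.testing.assert_array_equal(r1.loss_trace, r2.loss_trace)

    def test_predict_on_training_data_reproduces_training_risks(self, small_data):
        cfg = sp.TrainConfig(max_epochs=40)
        res = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        again = sp.predict(res.params, small_data.X, small_data.network)
        for b in small_data.labels.biomarkers:
            np.testing.assert_array_equal(res.risks.scores[b], again.scores[b])

    def test_permuting_samples_permutes_scores(self, small_data, rng):
        cfg = sp.TrainConfig(max_epochs=20)
        res = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        perm = rng.permutation(small_data.X.n_samples)
        X_perm = sp.ExpressionMatrix(
            small_data.X.values[:, perm],
            small_data.X.protein_ids,
            [small_data.X.sample_ids[j] for j in perm],
        )
        scores = sp.predict(res.params, small_data.X, small_data.network).scores
        scores_perm = sp.predict(res.params, X_perm, small_data.network).scores
        for b in scores:
            np.testing.assert_allclose(scores_perm[b], scores[b][perm], rtol=1e-12)

    def test_zero_theta_model_scores_half_everywhere(self, small_data):
        params = ModelParams(
            phi=np.ones(small_data.X.n_proteins),
            theta={"A": np.zeros(small_data.X.n_proteins)},
            protein_ids=small_data.X.protein_ids,
        )
        risks = sp.predict(params, small_data.X, small_data.network)
        np.testing.assert_allclose(risks.scores["A"], 0.5)

    def test_protein_mismatch_rejected(self, small_data):
        cfg = sp.TrainConfig(max_epochs=5)
        res = sp.fit(small_data.X, small_data.network, small_data.labels, cfg)
        X_bad = sp.ExpressionMatrix(
            small_data.X.values[:-1],
            small_data.X.protein_ids[:-1],
            small_data.X.sample_ids,
        )
        with pytest.raises(ValueError, match="protein set mismatch"):
            sp.predict(res.params, X_bad, small_data.network)

    def test_divergence_raises_informative_error(self, small_data):
        cfg = sp.TrainConfig(max_epochs=5000, optimizer="plain-gd", eta=1e4, tol=0.0)
        with pytest.raises((FloatingPointError, ValueError)):
            sp.fit(small_data.X, small_data.network, small_data.labels, cfg)

    def test_covariate_extension_improves_fit_when_signal_present(self):
        data = sp.make_dataset(
            sp.SyntheticSpec(d=10, n=400, seed=9, theta_scale=0.5,
                             n_covariates=2, covariate_scale=2.0)
        )
        base = sp.fit(data.X, data.network, data.labels, sp.TrainConfig(max_epochs=300, eta=0.01))
        ext = sp.fit(
            data.X, data.network, data.labels,
            sp.TrainConfig(max_epochs=300, eta=0.01, covariates_enabled=True),
            covariates=data.covariates,
        )
        assert ext.loss_trace[-1] < base.loss_trace[-1]
        risks = sp.predict(ext.params, data.X, data.network, covariates=data.covariates)
        for b in data.labels.biomarkers:
            assert 0 < risks.scores[b].min() and risks.scores[b].max() < 1
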