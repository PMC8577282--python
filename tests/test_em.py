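"""MAP-EM machinery: E-step, block M-steps, restarts, convergence."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from conftest import random_params
from dirgmm.em import (
    EmptyClusterError,
    FitConfig,
    covariance_penalty,
    e_step,
    fit,
    initialize,
    mean_update_system,
    update_directions,
    update_means,
    update_theta,
)
from dirgmm.model import (
    DirectionalGmmParams,
    GridSpec,
    complete_log_likelihood,
    prior_log_density,
)
from dirgmm.simulate import SimulationConfig, generate_dataset


class TestEStep:
    def test_identical_components_split_evenly(self, rng):
        params = random_params(rng, GridSpec(2, 1), 3)
        params.mu[1] = params.mu[0]
        params.Sigma[1] = params.Sigma[0]
        params.pi = np.array([0.5, 0.5])
        resp = e_step(rng.standard_normal((7, 3)), params)
        np.testing.assert_allclose(resp, 0.5)

    def test_single_cluster_gets_everything(self, rng):
        params = random_params(rng, GridSpec(1, 1), 2)
        params.pi = np.array([1.0])
        resp = e_step(rng.standard_normal((5, 2)), params)
        np.testing.assert_allclose(resp, 1.0)

    def test_matches_brute_force_bayes_oracle(self, rng):
        params = random_params(rng, GridSpec(3, 1), 2)
        X = rng.standard_normal((5, 2))
        resp = e_step(X, params)
        for b in range(5):
            joint = np.array(
                [
                    params.pi[s]
                    * multivariate_normal.pdf(X[b], params.mu[s], params.Sigma[s])
                    for s in range(3)
                ]
            )
            np.testing.assert_allclose(resp[b], joint / joint.sum(), atol=1e-10)

    def test_rows_sum_to_one(self, rng):
        params = random_params(rng, GridSpec(2, 2), 3)
        resp = e_step(rng.standard_normal((11, 3)), params)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)


def map_mean_objective(mu_flat, X, resp, grid, params):
    mu = mu_flat.reshape(params.mu.shape)
    obs = 0.0
    for s in range(mu.shape[0]):
        obs += resp[:, s] @ multivariate_normal.logpdf(X, mu[s], params.Sigma[s])
    work = DirectionalGmmParams(
        mu=mu, Sigma=params.Sigma, pi=params.pi, Delta=params.Delta, Q=params.Q,
        Q0=params.Q0, mu0=params.mu0, Delta_perp=params.Delta_perp,
    )
    return prior_log_density(mu, grid, work) + obs


class TestUpdateMeans:
    def test_uninformative_root_gives_weighted_mean(self, rng):
        grid = GridSpec(1, 1)
        params = random_params(rng, grid, 2)
        params.Q0 = np.eye(2) * 1e12
        X = rng.standard_normal((30, 2))
        resp = rng.dirichlet([1], size=30)  # all ones
        mu = update_means(X, resp, grid, params)
        np.testing.assert_allclose(mu[0], X.mean(axis=0), atol=1e-6)

    def test_uninformative_data_gives_prior_mode(self, rng):
        grid = GridSpec(3, 1)
        params = random_params(rng, grid, 2)
        params.Sigma = np.stack([np.eye(2) * 1e12] * 3)
        params.Q = np.eye(2) * 1e-6
        params.Q0 = np.eye(2) * 1e-6
        X = rng.standard_normal((9, 2))
        resp = np.full((9, 3), 1 / 3)
        mu = update_means(X, resp, grid, params)
        for i in range(3):
            np.testing.assert_allclose(mu[i], params.mu0 + i * params.Delta, atol=1e-4)

    @pytest.mark.parametrize("rows", [1, 2])
    def test_gradient_zero_and_multistart_optimality(self, rng, rows):
        grid = GridSpec(3, rows)
        params = random_params(rng, grid, 2)
        X = rng.standard_normal((15, 2)) * 2
        resp = rng.dirichlet(np.ones(grid.n_clusters), size=15)
        mu = update_means(X, resp, grid, params)
        A, b = mean_update_system(X, resp, grid, params)
        assert np.abs(b - A @ mu.ravel()).max() < 1e-6
        ours = map_mean_objective(mu.ravel(), X, resp, grid, params)
        for _ in range(10):
            x0 = rng.standard_normal(mu.size) * 3
            res = minimize(
                lambda m: -map_mean_objective(m, X, resp, grid, params), x0, method="BFGS"
            )
            assert -res.fun <= ours + 1e-5


class TestUpdateDirections:
    def test_two_cluster_chain_single_difference(self, rng):
        mu = rng.standard_normal((2, 4))
        delta, dperp = update_directions(mu, GridSpec(2, 1))
        np.testing.assert_allclose(delta, mu[1] - mu[0])
        assert dperp is None

    def test_telescoping_identity_and_optimizer_oracle(self, rng):
        grid = GridSpec(4, 1)
        mu = rng.standard_normal((4, 3))
        Q = np.eye(3) * 0.7
        delta, _ = update_directions(mu, grid, Q=Q)
        np.testing.assert_allclose(delta, (mu[3] - mu[0]) / 3, atol=1e-12)
        edge_sum = lambda dl: sum(
            multivariate_normal.logpdf(mu[i], mu[i - 1] + dl, Q) for i in range(1, 4)
        )
        res = minimize(lambda dl: -edge_sum(dl), np.zeros(3), method="BFGS")
        np.testing.assert_allclose(delta, res.x, atol=1e-5)

    def test_single_cluster_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            delta, dperp = update_directions(np.zeros((1, 3)), GridSpec(1, 1))
        np.testing.assert_array_equal(delta, 0.0)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_2d_orthogonality_exact(self, rng, K):
        grid = GridSpec(K, 2)
        mu = rng.standard_normal((2 * K, 3)) * 2
        delta, dperp = update_directions(mu, grid, Q=np.eye(3))
        assert abs(delta @ dperp) < 1e-10 * np.linalg.norm(delta) * np.linalg.norm(dperp)

    def test_2d_update_never_decreases_edge_objective(self, rng):
        from dirgmm.em import _edge_objective, _edge_stats

        grid = GridSpec(3, 2)
        mu = rng.standard_normal((6, 3))
        Q = np.eye(3)
        prev_delta = rng.standard_normal(3)
        prev_perp = rng.standard_normal(3)
        prev_perp -= (prev_perp @ prev_delta) / (prev_delta @ prev_delta) * prev_delta
        delta, dperp = update_directions(mu, grid, Q=Q, prev=(prev_delta, prev_perp))
        resids, coefs = _edge_stats(mu, grid)
        before = _edge_objective(resids, coefs, prev_delta, prev_perp, Q)
        after = _edge_objective(resids, coefs, delta, dperp, Q)
        assert after >= before - 1e-10


class TestUpdateTheta:
    def test_even_hard_assignment_weights(self, rng):
        grid = GridSpec(4, 1)
        X = rng.standard_normal((100, 2))
        resp = np.zeros((100, 4))
        resp[np.arange(100), np.repeat(np.arange(4), 25)] = 1.0
        mu = np.stack([X[resp[:, s] == 1].mean(axis=0) for s in range(4)])
        pi, _, _ = update_theta(X, resp, mu, grid, np.zeros(2), data_var=1.0)
        np.testing.assert_allclose(pi, 0.25)

    def test_sigma_is_shrunk_hard_scatter(self, rng):
        grid = GridSpec(2, 1)
        X = rng.standard_normal((40, 3))
        resp = np.zeros((40, 2))
        resp[:20, 0] = 1.0
        resp[20:, 1] = 1.0
        mu = np.stack([X[:20].mean(axis=0), X[20:].mean(axis=0)])
        data_var = float(np.var(X, axis=0).mean())
        _, Sigma, _ = update_theta(
            X, resp, mu, grid, np.zeros(3), cov_shrinkage=10.0, data_var=data_var
        )
        diff = X[:20] - mu[0]
        scatter = diff.T @ diff / 20
        expected = (20 * scatter + 10 * data_var * np.eye(3)) / 30
        np.testing.assert_allclose(Sigma[0], expected, atol=1e-12)

    def test_q_matches_hand_assembled_residual_formula(self, rng):
        grid = GridSpec(3, 1)
        mu = rng.standard_normal((3, 2))
        delta = rng.standard_normal(2)
        X = rng.standard_normal((9, 2))
        resp = np.full((9, 3), 1 / 3)
        data_var = float(np.var(X, axis=0).mean())
        _, _, Q = update_theta(X, resp, mu, grid, delta, ridge=1e-6, data_var=data_var)
        r2 = mu[1] - mu[0] - delta
        r3 = mu[2] - mu[1] - delta
        expected = (np.outer(r2, r2) + np.outer(r3, r3) + 1e-6 * data_var * np.eye(2)) / 3
        np.testing.assert_allclose(Q, expected, atol=1e-12)

    def test_empty_cluster_flagged(self, rng):
        grid = GridSpec(2, 1)
        X = rng.standard_normal((10, 2))
        resp = np.zeros((10, 2))
        resp[:, 0] = 1.0
        with pytest.raises(EmptyClusterError):
            update_theta(X, resp, X[:2].copy(), grid, np.zeros(2))


class TestInitialize:
    def test_responsibility_rows_sum_to_one(self, rng):
        data, _ = generate_dataset(
            SimulationConfig(grid=GridSpec(3, 1), D=8, n_samples=60, seed=5)
        )
        _, resp = initialize(data, GridSpec(3, 1), seed=1)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_initial_directions_orthogonal(self, rng):
        data, _ = generate_dataset(
            SimulationConfig(grid=GridSpec(2, 2), D=8, n_samples=80, seed=5)
        )
        params, _ = initialize(data, GridSpec(2, 2), seed=1)
        assert abs(params.Delta @ params.Delta_perp) <= 1e-8 * np.linalg.norm(
            params.Delta
        ) * np.linalg.norm(params.Delta_perp)

    def test_recovers_well_separated_clusters(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(grid=GridSpec(4, 1), D=12, n_samples=200, sd_scale=0.5, seed=3)
        data, truth = generate_dataset(cfg)
        params, resp = initialize(data, GridSpec(4, 1), seed=2)
        labels = np.argmax(resp, axis=1)
        assert adjusted_rand_score(truth.labels, labels) > 0.9


class TestFit:
    def test_recovers_near_noiseless_truth(self):
        cfg = SimulationConfig(
            grid=GridSpec(3, 1), D=10, n_samples=90, sd_scale=0.01, seed=11
        )
        data, truth = generate_dataset(cfg)
        res = fit(data, GridSpec(3, 1), FitConfig(n_init=5, seed=0))
        from dirgmm.evaluate import matched_rmse

        rmse = matched_rmse(truth.params.mu, res.params.mu, "grid", GridSpec(3, 1))
        assert rmse < 0.1  # 10x the noise scale

    def test_trace_monotone_and_convergence_rule(self):
        cfg = SimulationConfig(grid=GridSpec(3, 1), D=10, n_samples=120, seed=7)
        data, _ = generate_dataset(cfg)
        config = FitConfig(n_init=5, seed=1)
        res = fit(data, GridSpec(3, 1), config)
        trace = np.array(res.ecll_trace)
        assert np.all(np.diff(trace) >= -1e-6)
        assert res.converged
        rel = np.diff(trace)[-config.patience :] / np.abs(trace[-config.patience - 1 : -1])
        assert np.all(rel < config.rel_tol)

    def test_seeded_determinism_is_bitwise(self):
        cfg = SimulationConfig(grid=GridSpec(2, 1), D=8, n_samples=80, seed=3)
        data, _ = generate_dataset(cfg)
        a = fit(data, GridSpec(2, 1), FitConfig(n_init=4, seed=9))
        b = fit(data, GridSpec(2, 1), FitConfig(n_init=4, seed=9))
        np.testing.assert_array_equal(a.params.mu, b.params.mu)
        np.testing.assert_array_equal(a.params.Sigma, b.params.Sigma)
        np.testing.assert_array_equal(a.responsibilities, b.responsibilities)
        assert a.ecll_trace == b.ecll_trace

    def test_reported_delta_is_canonical(self):
        cfg = SimulationConfig(grid=GridSpec(3, 1), D=8, n_samples=90, seed=2)
        data, _ = generate_dataset(cfg)
        res = fit(data, GridSpec(3, 1), FitConfig(n_init=3, seed=4))
        assert res.params.Delta[0] >= 0


class TestBlockwiseAscent:
    def test_each_m_block_never_decreases_objective(self, rng):
        """One EM sweep, asserting ascent of the penalized objective per block."""
        grid = GridSpec(3, 1)
        cfg = SimulationConfig(grid=grid, D=6, n_samples=45, seed=13)
        data, _ = generate_dataset(cfg)
        X = data.x
        data_var = float(np.var(X, axis=0).mean())
        config = FitConfig(n_init=1, seed=0)
        params, _ = initialize(X, grid, seed=3, config=config)

        def objective(p, resp):
            return complete_log_likelihood(X, p.mu, resp, p, grid) + covariance_penalty(
                p.Sigma, p.Q, grid, config.cov_shrinkage, config.ridge, data_var
            )

        for _ in range(5):
            resp = e_step(X, params)
            base = objective(params, resp)
            mu = update_means(X, resp, grid, params)
            p1 = DirectionalGmmParams(
                mu=mu, Sigma=params.Sigma, pi=params.pi, Delta=params.Delta,
                Q=params.Q, Q0=params.Q0, mu0=params.mu0, Delta_perp=params.Delta_perp,
            )
            after_means = objective(p1, resp)
            assert after_means >= base - 1e-8 * abs(base)
            delta, dperp = update_directions(
                mu, grid, Q=params.Q, prev=(params.Delta, params.Delta_perp)
            )
            p2 = DirectionalGmmParams(
                mu=mu, Sigma=params.Sigma, pi=params.pi, Delta=delta,
                Q=params.Q, Q0=params.Q0, mu0=params.mu0, Delta_perp=dperp,
            )
            after_dirs = objective(p2, resp)
            assert after_dirs >= after_means - 1e-8 * abs(after_means)
            pi, Sigma, Q = update_theta(
                X, resp, mu, grid, delta, dperp,
                ridge=config.ridge, cov_shrinkage=config.cov_shrinkage, data_var=data_var,
            )
            params = DirectionalGmmParams(
                mu=mu, Sigma=Sigma, pi=pi, Delta=delta, Q=Q,
                Q0=params.Q0, mu0=params.mu0, Delta_perp=dperp,
            )
            after_theta = objective(params, resp)
            assert after_theta >= after_dirs - 1e-8 * abs(after_dirs)
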