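"""Unit tests of the likelihood layer, ICM, E/M steps and the full fit."""

import numpy as np
import pytest
from _reference import (
    dense_class_loglik,
    dense_conditional_moments,
    icm_by_hand,
    latent_gmm_em,
    q_function,
)

import drsc
from drsc.model import (
    FitOptions,
    class_logliks,
    class_marginal_loglik,
    estep_embeddings,
    fit_drsc,
    initialize_params,
    mstep_update,
    responsibilities,
    update_beta,
)
from drsc.neighbors import build_lattice_neighbors
from drsc.types import (
    ExpressionMatrix,
    InvalidParameterError,
    ModelParams,
    NeighborGraph,
)
from conftest import random_params


# ---------------------------------------------------------------------------
# class marginal log-likelihood
# ---------------------------------------------------------------------------

class TestClassMarginalLoglik:
    def test_standard_normal_case(self):
        params = ModelParams(W=[[0.0]], Lambda=[1.0], mu=[[0.0]], Sigma=[[1.0]])
        val = class_marginal_loglik(np.array([0.0]), params, 1)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("p,q,K", [(3, 2, 2), (8, 3, 3), (20, 5, 4)])
    def test_matches_dense_covariance_oracle(self, rng, p, q, K):
        params = random_params(rng, p, q, K)
        X = rng.standard_normal((6, p)) * 2.0
        ll = class_logliks(X, params)
        for i in range(6):
            for k in range(K):
                expect = dense_class_loglik(
                    X[i], params.W, params.Lambda, params.mu[k], params.Sigma[k]
                )
                assert ll[i, k] == pytest.approx(expect, abs=1e-8)

    def test_translation_invariance_in_column_space(self, rng):
        p, q = 6, 2
        W = np.linalg.qr(rng.standard_normal((p, q)))[0]
        params = ModelParams(
            W, np.full(p, 1.3), np.zeros((1, q)), np.eye(q)[None], 0.0
        )
        x = rng.standard_normal(p)
        d = rng.standard_normal(q)
        base = class_marginal_loglik(x, params, 1)
        shifted_params = ModelParams(
            W, params.Lambda, d[None, :], np.eye(q)[None], 0.0
        )
        shifted = class_marginal_loglik(x + W @ d, shifted_params, 1)
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_invalid_parameters_rejected(self, rng):
        p, q = 4, 2
        bad_sigma = ModelParams(
            rng.standard_normal((p, q)), np.ones(p), np.zeros((1, q)),
            np.array([[[1.0, 0.0], [0.0, -1.0]]]),
        )
        with pytest.raises(InvalidParameterError):
            class_marginal_loglik(np.zeros(p), bad_sigma, 1)
        bad_lam = ModelParams(
            rng.standard_normal((p, q)), np.array([1.0, 0.0, 1.0, 1.0]),
            np.zeros((1, q)), np.eye(q)[None],
        )
        with pytest.raises(InvalidParameterError):
            class_marginal_loglik(np.zeros(p), bad_lam, 1)


# ---------------------------------------------------------------------------
# ICM label sweeps
# ---------------------------------------------------------------------------

class TestIcmSweep:
    def _setup(self, rng, n=16, p=6, q=2, K=3, beta=1.0):
        params = random_params(rng, p, q, K, beta=beta)
        X = ExpressionMatrix(rng.standard_normal((n, p)))
        graph = build_lattice_neighbors(4, 4)
        return X, graph, params

    def test_beta_zero_reduces_to_independent_argmax(self, rng):
        X, graph, params = self._setup(rng, beta=0.0)
        y0 = rng.integers(1, 4, size=16)
        out = drsc.icm_sweep(X, graph, params, y0)
        ll = class_logliks(X.values, params)
        assert np.array_equal(out, np.argmax(ll, axis=1) + 1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_hand_simulated_coordinate_ascent_2x2(self, seed):
        rng = np.random.default_rng(seed)
        ll = rng.standard_normal((4, 2))
        y0 = rng.integers(0, 2, size=4)
        graph = build_lattice_neighbors(2, 2)
        neighbor_sets = [ns.tolist() for ns in graph.neighbor_sets()]
        assert neighbor_sets == [[1, 2], [0, 3], [0, 3], [1, 2]]
        expect = icm_by_hand(ll, 1.0, neighbor_sets, y0)
        from drsc.model import _icm_from_logliks

        got = _icm_from_logliks(ll, 1.0, graph, y0.astype(np.int64), 10)
        assert np.array_equal(got, expect)

    def test_uniform_labeling_is_fixed_point_under_huge_beta(self, rng):
        X, graph, params = self._setup(rng, beta=1e6)
        ll = np.zeros((16, 3))
        from drsc.model import _icm_from_logliks

        ones = np.zeros(16, dtype=np.int64)
        out = _icm_from_logliks(ll, 1e6, graph, ones, 10)
        assert np.array_equal(out, ones)


# ---------------------------------------------------------------------------
# responsibilities
# ---------------------------------------------------------------------------

class TestResponsibilities:
    def test_equal_logliks_give_uniform_rows(self, rng):
        n, p, q, K = 10, 4, 2, 3
        params = random_params(rng, p, q, K, beta=0.0)
        # identical classes -> identical logliks
        params.mu[:] = params.mu[0]
        params.Sigma[:] = params.Sigma[0]
        X = ExpressionMatrix(rng.standard_normal((n, p)))
        graph = NeighborGraph.empty(n)
        y = np.ones(n, dtype=int)
        R = responsibilities(X, graph, params, y)
        assert np.allclose(R, 1.0 / K, atol=1e-12)

    def test_three_spot_toy_matches_direct_softmax(self, rng):
        p, q, K = 5, 2, 2
        params = random_params(rng, p, q, K, beta=0.7)
        X = ExpressionMatrix(rng.standard_normal((3, p)))
        # path graph 0-1-2
        import scipy.sparse as sp

        adj = sp.csr_matrix(
            np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        )
        graph = NeighborGraph(adj)
        y = np.array([1, 2, 1])
        R = responsibilities(X, graph, params, y)
        ll = class_logliks(X.values, params)
        counts = np.array([[0.0, 1.0], [2.0, 0.0], [0.0, 1.0]])
        scores = ll + 0.7 * counts
        expect = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        assert np.allclose(R, expect, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_are_distributions(self, seed):
        rng = np.random.default_rng(seed)
        n, p, q, K = 30, 6, 2, 4
        params = random_params(rng, p, q, K, beta=rng.uniform(0, 3))
        X = ExpressionMatrix(rng.standard_normal((n, p)) * 3)
        graph = build_lattice_neighbors(5, 6)
        y = rng.integers(1, K + 1, size=n)
        R = responsibilities(X, graph, params, y)
        assert np.all(R >= 0) and np.all(R <= 1)
        assert np.allclose(R.sum(axis=1), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# E-step posterior moments
# ---------------------------------------------------------------------------

class TestEstepEmbeddings:
    def test_zero_loading_returns_prior_moments(self, rng):
        n, p, q, K = 8, 5, 2, 3
        params = random_params(rng, p, q, K)
        params.W[:] = 0.0
        X = ExpressionMatrix(rng.standard_normal((n, p)))
        R = np.full((n, K), 1.0 / K)
        m, S, z_hat = estep_embeddings(X, params, R)
        for k in range(K):
            assert np.allclose(m[:, k, :], params.mu[k], atol=1e-10)
            assert np.allclose(S[k], params.Sigma[k], atol=1e-10)

    def test_noiseless_identity_readout(self, rng):
        q = 3
        params = ModelParams(
            np.eye(q), np.full(q, 1e-8), np.zeros((1, q)), np.eye(q)[None]
        )
        X = rng.standard_normal((6, q))
        R = np.ones((6, 1))
        m, S, z_hat = estep_embeddings(X, params, R)
        assert np.allclose(m[:, 0, :], X, atol=1e-6)
        assert np.allclose(z_hat, X, atol=1e-6)

    def test_matches_dense_conditioning_oracle(self, rng):
        p, q, K = 2, 1, 2
        params = random_params(rng, p, q, K)
        X = rng.standard_normal((5, p))
        R = np.full((5, K), 0.5)
        m, S, _ = estep_embeddings(X, params, R)
        for i in range(5):
            for k in range(K):
                me, Se = dense_conditional_moments(
                    X[i], params.W, params.Lambda, params.mu[k], params.Sigma[k]
                )
                assert np.allclose(m[i, k], me, atol=1e-8)
                assert np.allclose(S[k], Se, atol=1e-8)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

class TestMstepUpdate:
    def test_single_cluster_mean_is_weighted_mean(self, rng):
        n, p, q = 20, 4, 2
        params = random_params(rng, p, q, 1)
        X = ExpressionMatrix(rng.standard_normal((n, p)))
        R = np.ones((n, 1))
        m, S, _ = estep_embeddings(X, params, R)
        new = mstep_update(X, R, m, S, params)
        assert np.allclose(new.mu[0], m[:, 0, :].mean(axis=0), atol=1e-10)

    def test_q_function_does_not_decrease(self, rng):
        n, p, q, K = 40, 6, 2, 2
        params = random_params(rng, p, q, K)
        X = rng.standard_normal((n, p)) * 2
        ll = class_logliks(X, params)
        R = np.exp(ll - ll.max(axis=1, keepdims=True))
        R /= R.sum(axis=1, keepdims=True)
        m, S, _ = estep_embeddings(X, params, R)
        q_before = q_function(
            X, R, m, S, params.W, params.Lambda, params.mu, params.Sigma
        )
        new = mstep_update(X, R, m, S, params)
        q_after = q_function(X, R, m, S, new.W, new.Lambda, new.mu, new.Sigma)
        assert q_after >= q_before - 1e-8 * abs(q_before)

    def test_loading_gradient_vanishes_at_update(self, rng):
        n, p, q, K = 50, 5, 2, 2
        params = random_params(rng, p, q, K)
        X = rng.standard_normal((n, p))
        R = rng.dirichlet(np.ones(K), size=n)
        m, S, _ = estep_embeddings(X, params, R)
        new = mstep_update(X, R, m, S, params)

        def q_of_w(Wf):
            return q_function(
                X, R, m, S, Wf.reshape(p, q), new.Lambda, new.mu, new.Sigma
            )

        w0 = new.W.ravel()
        h = 1e-5
        grad = np.empty(w0.size)
        for j in range(w0.size):
            wp, wm = w0.copy(), w0.copy()
            wp[j] += h
            wm[j] -= h
            grad[j] = (q_of_w(wp) - q_of_w(wm)) / (2 * h)
        assert np.max(np.abs(grad)) < 1e-4

    def test_empty_cluster_keeps_previous_parameters(self, rng):
        n, p, q, K = 20, 4, 2, 3
        params = random_params(rng, p, q, K)
        X = ExpressionMatrix(rng.standard_normal((n, p)))
        R = np.zeros((n, K))
        R[:, 0] = 0.6
        R[:, 1] = 0.4  # cluster 3 gets exactly zero mass
        m, S, _ = estep_embeddings(X, params, R)
        new = mstep_update(X, R, m, S, params)
        assert np.allclose(new.mu[2], params.mu[2])
        assert np.allclose(new.Sigma[2], params.Sigma[2])
        assert new.mu.shape[0] == K


# ---------------------------------------------------------------------------
# beta grid update
# ---------------------------------------------------------------------------

class TestUpdateBeta:
    def test_empty_graph_short_circuits_to_zero(self, rng):
        R = rng.dirichlet(np.ones(3), size=10)
        y = rng.integers(1, 4, size=10)
        assert update_beta(NeighborGraph.empty(10), R, y, [0.5, 1.0]) == 0.0

    def test_result_is_grid_member_and_matches_brute_force(self, rng):
        graph = build_lattice_neighbors(6, 6)
        n, K = 36, 3
        y = rng.integers(1, K + 1, size=n)
        R = rng.dirichlet(np.ones(K), size=n)
        grid = np.array([0.0, 0.3, 0.9, 1.7, 2.2])
        got = update_beta(graph, R, y, grid)
        assert got in grid
        # brute force: recompute PL(beta) point by point from scratch
        counts = graph.label_counts(y - 1, K)
        from scipy.special import logsumexp

        def pl(b):
            return np.sum(R * (b * counts)) - np.sum(logsumexp(b * counts, axis=1))

        vals = [pl(b) for b in grid]
        assert got == grid[int(np.argmax(vals))]

    def test_iid_labels_select_smallest_beta_in_majority(self):
        grid = np.array([0.0, 0.5, 1.0, 2.0])
        graph = build_lattice_neighbors(20, 20)
        n, K = 400, 4
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(1, K + 1, size=n)
            R = np.zeros((n, K))
            R[np.arange(n), y - 1] = 1.0
            if update_beta(graph, R, y, grid) == 0.0:
                hits += 1
        assert hits > 10


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

class TestFitDrsc:
    def test_objective_trace_non_decreasing(self, small_mixture_data):
        em, y_true, _ = small_mixture_data
        graph = build_lattice_neighbors(10, 15)
        fit = fit_drsc(em, graph, K=3, q=2, options=FitOptions(seed=0))
        tr = fit.objective_trace
        assert np.all(np.diff(tr) >= -1e-6 * (np.abs(tr[:-1]) + 1.0))

    def test_labels_are_argmax_of_responsibilities(self, small_mixture_data):
        em, _, _ = small_mixture_data
        fit = fit_drsc(em, None, K=3, q=2, options=FitOptions(seed=0))
        assert np.array_equal(fit.labels, np.argmax(fit.responsibilities, axis=1) + 1)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)

    def test_empty_graph_matches_latent_gmm_reference(self, small_mixture_data):
        em, _, _ = small_mixture_data
        fit = fit_drsc(em, None, K=3, q=2, options=FitOptions(seed=0))
        params0, _ = initialize_params(em, K=3, q=2, seed=0, spatial=False)
        ref_obj, ref_trace = latent_gmm_em(em.values, params0)
        assert fit.objective_trace[-1] == pytest.approx(ref_obj, abs=1e-6)

    def test_label_permutation_equivariance(self, small_mixture_data):
        em, _, _ = small_mixture_data
        rng = np.random.default_rng(3)
        y0 = rng.integers(1, 4, size=em.n_spots)
        perm = np.array([3, 1, 2])  # sigma(k) for k = 1..3
        fit_a = fit_drsc(em, None, 3, 2, FitOptions(seed=0, init=y0))
        fit_b = fit_drsc(em, None, 3, 2, FitOptions(seed=0, init=perm[y0 - 1]))
        assert np.array_equal(perm[fit_a.labels - 1], fit_b.labels)
        assert fit_a.objective_trace[-1] == pytest.approx(
            fit_b.objective_trace[-1], rel=1e-9
        )

    def test_spatial_fit_recovers_smooth_clusters(self):
        from drsc.simulate import simulate_sim1

        em, graph, truth = simulate_sim1(rows=20, cols=20, K=3, q=4, p=80, seed=5)
        fit = fit_drsc(em, graph, K=3, q=4, options=FitOptions(seed=5))
        assert drsc.ari(truth.y, fit.labels) > 0.5
        assert fit.params.beta > 0

    def test_input_validation(self, small_mixture_data):
        em, _, _ = small_mixture_data
        with pytest.raises(ValueError):
            fit_drsc(em, None, K=0, q=2)
        with pytest.raises(ValueError):
            fit_drsc(em, None, K=3, q=em.n_genes)
        with pytest.raises(ValueError):
            fit_drsc(em, NeighborGraph.empty(3), K=3, q=2)
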