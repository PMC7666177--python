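"""Optimizer tests: hand-evaluated objectives, exact block minimizers
against brute-force/sampling oracles, and descent/constraint invariants."""

from itertools import product

import numpy as np
import pytest

import pseudotree as pt
from pseudotree.ddrtree import (
    DDRTreeParams,
    LatentTreeModel,
    check_model,
    initialize,
    objective,
    update_B,
    update_R,
    update_W,
    update_Y,
    update_Z,
)


def _params(**kw):
    defaults = dict(d=2, K=2, lambda_=1.0, gamma_=1.0, sigma_=0.5, seed=0)
    defaults.update(kw)
    return DDRTreeParams(**defaults)


def _orthonormal(genes, d, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((genes, d)))
    return q


def _random_state(seed, genes=12, N=15, K=5, d=2):
    """A random constraint-satisfying model plus matching centered data."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((genes, N))
    X -= X.mean(axis=1, keepdims=True)
    W = _orthonormal(genes, d, seed)
    Z = rng.standard_normal((d, N))
    Y = rng.standard_normal((d, K))
    B = update_B(Y)
    R = rng.uniform(0.1, 1.0, size=(N, K))
    R /= R.sum(axis=1, keepdims=True)
    params = _params(K=K, lambda_=2.0, gamma_=3.0, sigma_=0.7)
    return X, LatentTreeModel(W=W, Z=Z, Y=Y, B=B, R=R, params=params), params


class TestObjective:
    def test_hand_case_tree_term_only(self):
        # exact reconstruction, one-hot R with z_i on its center, two
        # centers at distance 1, lambda=1: J = (1/2) * 2 edges * 1 = 1
        W = _orthonormal(3, 2)
        Y = np.array([[0.0, 1.0], [0.0, 0.0]])
        Z = Y.copy()
        X = W @ Z
        R = np.eye(2)
        model = LatentTreeModel(W=W, Z=Z, Y=Y, B=update_B(Y), R=R, params=None)
        J = objective(X, model, _params(lambda_=1.0, gamma_=2.0, sigma_=0.5))
        np.testing.assert_allclose(J, 1.0, atol=1e-12)

    def test_reconstruction_term_isolated(self):
        # lambda = 0 and a one-hot R with every z on its own center kills
        # the tree and clustering terms exactly (entropy of one-hot is 0)
        rng = np.random.default_rng(1)
        W = _orthonormal(6, 2, 1)
        Z = rng.standard_normal((2, 4))
        X = rng.standard_normal((6, 4))
        model = LatentTreeModel(
            W=W, Z=Z, Y=Z.copy(), B=update_B(Z), R=np.eye(4), params=None
        )
        J = objective(X, model, _params(K=4, lambda_=0.0, gamma_=5.0, sigma_=0.5))
        np.testing.assert_allclose(J, np.sum((X - W @ Z) ** 2), atol=1e-10)

    def test_uniform_assignment_entropy_closed_form(self):
        K, N = 4, 6
        W = _orthonormal(5, 2)
        Z = np.zeros((2, N))
        Y = np.zeros((2, K))
        B = np.zeros((K, K), dtype=int)
        B[0, 1:] = B[1:, 0] = 1  # star spanning tree on coincident centers
        R = np.full((N, K), 1.0 / K)
        model = LatentTreeModel(W=W, Z=Z, Y=Y, B=B, R=R, params=None)
        gamma, sigma = 2.0, 0.3
        J = objective(np.zeros((5, N)), model, _params(K=K, lambda_=1.0, gamma_=gamma, sigma_=sigma))
        np.testing.assert_allclose(J, gamma * sigma * N * np.log(1.0 / K), atol=1e-12)

    def test_invalid_model_rejected(self):
        X, model, params = _random_state(0)
        model.R = model.R * 2  # rows no longer sum to 1
        with pytest.raises(ValueError):
            objective(X, model, params)


class TestUpdateR:
    def test_equidistant_centers_split_evenly(self):
        Z = np.array([[0.0], [0.0]])
        Y = np.array([[-1.0, 1.0], [0.0, 0.0]])
        R = update_R(Z, Y, sigma_=0.7)
        np.testing.assert_allclose(R, [[0.5, 0.5]], atol=1e-12)

    def test_small_sigma_is_one_hot(self):
        Z = np.array([[0.1], [0.0]])
        Y = np.array([[0.0, 1.0], [0.0, 0.0]])
        R = update_R(Z, Y, sigma_=1e-8)
        np.testing.assert_allclose(R, [[1.0, 0.0]], atol=1e-12)

    def test_direct_evaluation(self):
        sigma = 0.5
        Z = np.array([[0.0], [0.0]])
        # squared distances (0, 2*sigma) -> r = (1, e^-2) normalized
        Y = np.array([[0.0, np.sqrt(2 * sigma)], [0.0, 0.0]])
        R = update_R(Z, Y, sigma_=sigma)
        expected = np.array([1.0, np.exp(-2.0)])
        expected /= expected.sum()
        np.testing.assert_allclose(R[0], expected, atol=1e-12)

    def test_rows_on_simplex(self, rng):
        Z = rng.standard_normal((2, 40))
        Y = rng.standard_normal((2, 7))
        R = update_R(Z, Y, sigma_=1e-3)
        assert (R >= 0).all()
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-12)


def _all_labeled_trees(K):
    """Enumerate all labeled spanning trees on K vertices by decoding
    every Pruefer sequence (Cayley: K^(K-2) trees)."""
    import heapq

    for seq in product(range(K), repeat=K - 2):
        degree = [1] * K
        for v in seq:
            degree[v] += 1
        leaves = [i for i in range(K) if degree[i] == 1]
        heapq.heapify(leaves)
        edges = []
        for v in seq:
            leaf = heapq.heappop(leaves)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(leaves, v)
        u = heapq.heappop(leaves)
        w = heapq.heappop(leaves)
        edges.append((u, w))
        yield edges


class TestUpdateB:
    def test_collinear_chain(self):
        Y = np.array([[0.0, 1.0, 2.5]])
        B = update_B(Y)
        assert B[0, 1] == 1 and B[1, 2] == 1 and B[0, 2] == 0

    def test_single_center_empty(self):
        assert update_B(np.zeros((2, 1))).sum() == 0

    def test_matches_exhaustive_enumeration(self, rng):
        K = 6
        Y = rng.standard_normal((2, K))
        D2 = ((Y.T[:, None, :] - Y.T[None, :, :]) ** 2).sum(-1)
        B = update_B(Y)
        mst_weight = (B * D2).sum() / 2
        best = np.inf
        for edges in _all_labeled_trees(K):
            w = sum(D2[i, j] for i, j in edges)
            best = min(best, w)
        np.testing.assert_allclose(mst_weight, best, atol=1e-10)


class TestUpdateY:
    def test_single_center_is_mean(self, rng):
        Z = rng.standard_normal((2, 9))
        R = np.ones((9, 1))
        B = np.zeros((1, 1), dtype=int)
        Y = update_Y(Z, R, B, lambda_=3.0, gamma_=2.0)
        np.testing.assert_allclose(Y[:, 0], Z.mean(axis=1), atol=1e-10)

    def test_lambda_zero_gives_weighted_means(self, rng):
        Z = rng.standard_normal((2, 12))
        R = rng.uniform(0.1, 1, size=(12, 3))
        R /= R.sum(axis=1, keepdims=True)
        Y = update_Y(Z, R, update_B(rng.standard_normal((2, 3))), lambda_=0.0, gamma_=4.0)
        expected = (Z @ R) / R.sum(axis=0)
        np.testing.assert_allclose(Y, expected, atol=1e-10)

    def test_solves_stationarity_and_descends(self):
        X, model, params = _random_state(3, N=10, K=4)
        before = objective(X, model, params)
        Y = update_Y(model.Z, model.R, model.B, params.lambda_, params.gamma_)
        L = np.diag(model.B.sum(axis=1)) - model.B
        A = params.lambda_ * L + params.gamma_ * np.diag(model.R.sum(axis=0))
        resid = Y @ A - params.gamma_ * model.Z @ model.R
        assert np.abs(resid).max() < 1e-10
        model.Y = Y
        model.B = update_B(Y)  # keep B optimal for the tree term
        assert objective(X, model, params) <= before + 1e-8


class TestUpdateZ:
    def test_small_gamma_is_projection(self, rng):
        X = rng.standard_normal((6, 5))
        W = _orthonormal(6, 2, 2)
        Z = update_Z(X, W, np.zeros((2, 3)), np.full((5, 3), 1 / 3), gamma_=1e-12)
        np.testing.assert_allclose(Z, W.T @ X, atol=1e-9)

    def test_hand_arithmetic_gamma_one(self):
        X = np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        W = np.eye(2)
        Y = np.array([[1.0], [1.0]])
        R = np.ones((3, 1))
        Z = update_Z(X, W, Y, R, gamma_=1.0)
        np.testing.assert_allclose(Z, (X + Y @ R.T) / 2.0)


class TestUpdateW:
    def test_recovers_orthonormal_factor(self, rng):
        Z = rng.standard_normal((3, 8))
        Q = _orthonormal(10, 3, 4)
        X = Q @ Z
        W = update_W(X, Z, d=3)
        np.testing.assert_allclose(W @ (W.T @ X), X, atol=1e-8)

    def test_beats_random_orthonormal_and_descends(self, rng):
        X = rng.standard_normal((20, 9))
        Z = rng.standard_normal((3, 9))
        W = update_W(X, Z, d=3)
        trace = np.trace(W.T @ X @ Z.T)
        for s in range(300):
            Wr = _orthonormal(20, 3, s + 100)
            assert trace >= np.trace(Wr.T @ X @ Z.T) - 1e-9
        W_old = _orthonormal(20, 3, 999)
        t1_old = np.sum((X - W_old @ Z) ** 2)
        assert np.sum((X - W @ Z) ** 2) <= t1_old + 1e-9


class TestInitialize:
    def test_rank2_data_has_zero_reconstruction(self, rng):
        W_true = _orthonormal(30, 2, 5)
        X = W_true @ rng.standard_normal((2, 25))
        Xc, model = initialize(X, DDRTreeParams(K=5, seed=0))
        term1 = np.sum((Xc - model.W @ model.Z) ** 2)
        assert term1 < 1e-18 * np.sum(Xc**2) + 1e-12

    def test_same_seed_bit_identical(self, rng):
        X = rng.standard_normal((30, 25))
        _, m1 = initialize(X, DDRTreeParams(K=6, seed=3))
        _, m2 = initialize(X, DDRTreeParams(K=6, seed=3))
        for attr in ("W", "Z", "Y", "B", "R"):
            np.testing.assert_array_equal(getattr(m1, attr), getattr(m2, attr))

    def test_gene_space_rotation_invariance(self, rng):
        X = rng.standard_normal((40, 30))
        Q = _orthonormal(40, 40, 8)
        _, m1 = initialize(X, DDRTreeParams(K=6, seed=2))
        _, m2 = initialize(Q @ X, DDRTreeParams(K=6, seed=2))
        np.testing.assert_allclose(m1.Z, m2.Z, atol=1e-6)
        np.testing.assert_allclose(m1.Y, m2.Y, atol=1e-6)

    def test_K_exceeding_N_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize(rng.standard_normal((10, 4)), DDRTreeParams(K=5, seed=0))


class TestFit:
    def test_objective_trace_monotone(self, fitted_path):
        _, _, model = fitted_path
        tr = np.array(model.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_noiseless_path_converges_quickly(self):
        cohort, _ = pt.simulate_cohort(
            topology="path", n_samples=100, n_genes=200, seed=1,
            plant_resistance=False, noise_sd=1e-6,
            frac_increasing=0, frac_decreasing=0, frac_branch_specific=0,
        )
        model = pt.fit(cohort.log_expression, DDRTreeParams(seed=1, tol=1e-5))
        assert len(model.objective_trace) - 1 <= 60  # converged well before max_iter

    def test_infinite_tol_runs_one_sweep(self, rng):
        X = rng.standard_normal((20, 15))
        model = pt.fit(X, DDRTreeParams(K=4, tol=np.inf, seed=0))
        assert len(model.objective_trace) == 2  # initial value + one sweep

    def test_final_model_satisfies_constraints(self, fitted_path):
        _, _, model = fitted_path
        check_model(model)
        assert model.B.sum() // 2 == model.n_centers - 1


@pytest.mark.parametrize("seed", range(20))
def test_each_block_update_never_increases_objective(seed):
    X, model, params = _random_state(seed)
    J0 = objective(X, model, params)
    # R block
    m = LatentTreeModel(**{**model.__dict__})
    m.R = update_R(m.Z, m.Y, params.sigma_)
    assert objective(X, m, params) <= J0 + 1e-8 * abs(J0)
    # B block
    m = LatentTreeModel(**{**model.__dict__})
    m.B = update_B(m.Y)
    assert objective(X, m, params) <= J0 + 1e-8 * abs(J0)
    # Y block (B re-optimized afterwards would also descend; Y alone is exact)
    m = LatentTreeModel(**{**model.__dict__})
    m.Y = update_Y(m.Z, m.R, m.B, params.lambda_, params.gamma_)
    assert objective(X, m, params) <= J0 + 1e-8 * abs(J0)
    # Z block
    m = LatentTreeModel(**{**model.__dict__})
    m.Z = update_Z(X, m.W, m.Y, m.R, params.gamma_)
    assert objective(X, m, params) <= J0 + 1e-8 * abs(J0)
    # W block
    m = LatentTreeModel(**{**model.__dict__})
    m.W = update_W(X, m.Z, params.d)
    assert objective(X, m, params) <= J0 + 1e-8 * abs(J0)


def test_scale_consistency_of_latent_geometry(rng):
    """Doubling X doubles the latent geometry when the entropy bandwidth
    is rescaled by c^2 (all objective terms then scale by c^2)."""
    X = rng.standard_normal((40, 30))
    c = 2.0
    p1 = DDRTreeParams(K=6, seed=4, sigma_=1e-3, max_iter=20, lambda_=6.0)
    p2 = DDRTreeParams(K=6, seed=4, sigma_=1e-3 * c**2, max_iter=20, lambda_=6.0)
    m1 = pt.fit(X, p1)
    m2 = pt.fit(c * X, p2)
    np.testing.assert_allclose(m2.Z, c * m1.Z, rtol=1e-5, atol=1e-6)
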