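"""Decomposition objective, block solvers and the alternating fit."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.optimize import minimize

from iscluster import (
    Decomposition,
    Dimensions,
    ViewSet,
    fit_isc,
    objective,
    simulate_two_view,
    solve_basis,
    solve_common,
    solve_specific,
)
from conftest import planted_instance, random_decomposition, random_orthonormal


def brute_objective(Xs, P, C, S, beta, d0):
    """Independent elementwise evaluation of the fitted objective."""
    n = C.shape[1]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    total = 0.0
    for X, P_v, S_v in zip(Xs, P, S):
        Z = np.vstack([C, S_v])
        total += np.sum((X - P_v @ Z) ** 2)
        total += beta * np.trace(C.T @ C @ H @ S_v.T @ S_v @ H)
    return float(total)


class TestObjective:
    def test_zero_residual_zero_beta(self, rng):
        views, P, C, S = planted_instance(rng)
        dec = Decomposition(P=P, C=C, S=S, d0=2)
        dims = Dimensions(2, (2, 1), beta=0.0)
        assert objective(views, dec, dims) == pytest.approx(0.0, abs=1e-18)

    def test_zero_representations_give_total_energy(self, rng):
        views, P, C, S = planted_instance(rng)
        dec = Decomposition(
            P=P, C=np.zeros_like(C), S=[np.zeros_like(s) for s in S], d0=2
        )
        dims = Dimensions(2, (2, 1), beta=7.0)
        energy = sum(np.sum(X**2) for X in views.views)
        assert objective(views, dec, dims) == pytest.approx(energy, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        views = ViewSet([rng.standard_normal((3, 4))])
        dec = random_decomposition(rng, views, d0=1, d_spec=(1,))
        dims = Dimensions(1, (1,), beta=0.7)
        expected = brute_objective(views.views, dec.P, dec.C, dec.S, 0.7, 1)
        assert objective(views, dec, dims) == pytest.approx(expected, rel=1e-10)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            ViewSet([np.array([[1.0, np.inf], [0.0, 1.0]])])


def specific_residual(v, views, dec, dims, S_v):
    """Residual of the specific-part stationarity (Sylvester) equation."""
    P_c, P_s = dec.P_common(v), dec.P_specific(v)
    n = views.n
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    lhs = P_s.T @ P_s @ S_v + dims.beta * S_v @ H @ dec.C.T @ dec.C @ H
    rhs = P_s.T @ views[v] - P_s.T @ P_c @ dec.C
    return np.linalg.norm(lhs - rhs) / (1.0 + np.linalg.norm(rhs))


class TestSolveSpecific:
    def test_exact_reconstruction_recovered(self, rng):
        views, P, C, S = planted_instance(rng)
        dec = Decomposition(P=P, C=C, S=[np.zeros_like(s) for s in S], d0=2)
        dims = Dimensions(2, (2, 1), beta=0.0)
        for v in range(2):
            np.testing.assert_allclose(
                solve_specific(v, views, dec, dims), S[v], atol=1e-10
            )

    @pytest.mark.parametrize("method", ["reduced", "sylvester"])
    def test_defining_equation_residual(self, rng, method):
        views = ViewSet([rng.standard_normal((5, 8)) for _ in range(2)])
        dec = random_decomposition(rng, views, d0=2, d_spec=(2, 2))
        dims = Dimensions(2, (2, 2), beta=0.5)
        for v in range(2):
            S_v = solve_specific(v, views, dec, dims, method=method)
            assert specific_residual(v, views, dec, dims, S_v) < 1e-8

    def test_reduced_and_sylvester_agree(self, rng):
        views = ViewSet([rng.standard_normal((4, 6))])
        dec = random_decomposition(rng, views, d0=1, d_spec=(2,))
        dims = Dimensions(1, (2,), beta=1.3)
        a = solve_specific(0, views, dec, dims, method="reduced")
        b = solve_specific(0, views, dec, dims, method="sylvester")
        np.testing.assert_allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_derivative_free_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        views = ViewSet([rng.standard_normal((3, 4))])
        dec = random_decomposition(rng, views, d0=1, d_spec=(1,))
        dims = Dimensions(1, (1,), beta=0.5)
        S_opt = solve_specific(0, views, dec, dims)

        def f(x):
            return brute_objective(
                views.views, dec.P, dec.C, [x.reshape(1, 4)], 0.5, 1
            )

        res = minimize(f, np.zeros(4), method="Powell", options={"maxfev": 20000})
        assert f(S_opt.ravel()) <= res.fun + 1e-5


class TestSolveBasis:
    def test_perfect_fit_attainable(self, rng):
        n, d = 6, 3
        Z = rng.standard_normal((d, n))
        Q = random_orthonormal(rng, 5, d)
        views = ViewSet([Q @ Z])
        dec = Decomposition(P=[Q], C=Z[:2], S=[Z[2:]], d0=2)
        P_new = solve_basis(0, views, dec)
        assert np.linalg.norm(views[0] - P_new @ Z) < 1e-10

    def test_orthonormality(self, rng):
        views = ViewSet([rng.standard_normal((6, 9))])
        dec = random_decomposition(rng, views, d0=2, d_spec=(2,))
        P_new = solve_basis(0, views, dec)
        defect = np.abs(P_new.T @ P_new - np.eye(4)).max()
        assert defect < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_angle_grid_oracle(self, seed):
        # p = 2, d = 1: exhaustive search over P = (cos t, sin t)^T
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((2, 5))
        Z = rng.standard_normal((1, 5))
        views = ViewSet([X])
        dec = Decomposition(P=[np.eye(2)[:, :1]], C=Z, S=[np.zeros((0, 5))], d0=1)
        P_new = solve_basis(0, views, dec)
        theta = np.linspace(0, 2 * np.pi, 10**6, endpoint=False)
        cand = np.stack([np.cos(theta), np.sin(theta)])  # 2 x grid
        obj = ((X[:, :, None] - cand[:, None, :] * Z.T[None, :, :]) ** 2).sum((0, 1))
        assert np.sum((X - P_new @ Z) ** 2) <= obj.min() + 1e-6

    def test_rank_deficient_warns(self, rng):
        views = ViewSet([np.zeros((4, 5)) + 0.0])
        dec = random_decomposition(rng, views, d0=1, d_spec=(1,))
        with pytest.warns(UserWarning):
            P_new = solve_basis(0, views, dec)
        assert np.abs(P_new.T @ P_new - np.eye(2)).max() < 1e-10


def common_residual(views, dec, dims, C):
    n = views.n
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    A = sum(dec.P_common(v).T @ dec.P_common(v) for v in range(views.V))
    B = dims.beta * sum(H @ S_v.T @ S_v @ H for S_v in dec.S)
    rhs = sum(
        dec.P_common(v).T @ views[v] - dec.P_common(v).T @ dec.P_specific(v) @ dec.S[v]
        for v in range(views.V)
    )
    return np.linalg.norm(A @ C + C @ B - rhs) / (1.0 + np.linalg.norm(rhs))


class TestSolveCommon:
    def test_exact_reconstruction_recovered(self, rng):
        views, P, C, S = planted_instance(rng)
        dec = Decomposition(P=P, C=np.zeros_like(C), S=S, d0=2)
        dims = Dimensions(2, (2, 1), beta=0.0)
        np.testing.assert_allclose(solve_common(views, dec, dims), C, atol=1e-10)

    @pytest.mark.parametrize("method", ["reduced", "sylvester"])
    def test_defining_equation_residual(self, rng, method):
        views = ViewSet([rng.standard_normal((5, 7)) for _ in range(2)])
        dec = random_decomposition(rng, views, d0=2, d_spec=(1, 2))
        dims = Dimensions(2, (1, 2), beta=0.3)
        C = solve_common(views, dec, dims, method=method)
        assert common_residual(views, dec, dims, C) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_derivative_free_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        views = ViewSet([rng.standard_normal((3, 4)) for _ in range(2)])
        dec = random_decomposition(rng, views, d0=1, d_spec=(1, 1))
        dims = Dimensions(1, (1, 1), beta=0.3)
        C_opt = solve_common(views, dec, dims)

        def f(x):
            return brute_objective(
                views.views, dec.P, x.reshape(1, 4), dec.S, 0.3, 1
            )

        res = minimize(f, np.zeros(4), method="Powell", options={"maxfev": 20000})
        assert f(C_opt.ravel()) <= res.fun + 1e-5


class TestFitIsc:
    def test_planted_noiseless_reaches_zero_objective(self, rng):
        views, P_true, C_true, S_true = planted_instance(rng)
        dec = fit_isc(views, Dimensions(2, (2, 1), beta=0.0))
        energy = sum(np.sum(X**2) for X in views.views)
        assert dec.objective_trace[-1] < 1e-6 * energy

    def test_planted_subspace_recovered(self, rng):
        views, P_true, _, _ = planted_instance(rng)
        dec = fit_isc(views, Dimensions(2, (2, 1), beta=0.0))
        for v in range(views.V):
            angles = subspace_angles(dec.P[v], P_true[v])
            assert angles.max() < 1e-3

    @pytest.mark.parametrize("t,seed", [(0.1, 0), (2.0, 1), (10.0, 2)])
    def test_trace_monotone_on_simulated_data(self, t, seed):
        b = simulate_two_view(t, seed, n=80)
        dec = fit_isc(ViewSet(b.X), Dimensions(2, (2, 2), beta=1.0))
        tr = np.array(dec.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9)
        assert tr[-1] >= 0.0

    def test_orthonormal_after_fit(self, rng):
        b = simulate_two_view(5.0, 3, n=60)
        dec = fit_isc(ViewSet(b.X), Dimensions(2, (2, 2), beta=0.1))
        assert dec.orthonormality_defect() < 1e-8

    def test_reproducible_given_seed(self):
        b = simulate_two_view(2.0, 5, n=60)
        d1 = fit_isc(ViewSet(b.X), Dimensions(2, (2, 2), 0.5), seed=9)
        d2 = fit_isc(ViewSet(b.X), Dimensions(2, (2, 2), 0.5), seed=9)
        np.testing.assert_array_equal(d1.C, d2.C)
        for v in range(2):
            np.testing.assert_array_equal(d1.P[v], d2.P[v])
            np.testing.assert_array_equal(d1.S[v], d2.S[v])
        assert d1.objective_trace == d2.objective_trace

    def test_permutation_equivariance(self, rng):
        b = simulate_two_view(1.0, 4, n=40)
        views = ViewSet(b.X)
        dims = Dimensions(2, (2, 2), beta=0.0)
        perm = rng.permutation(40)
        dec = fit_isc(views, dims, n_init=1)
        dec_p = fit_isc(ViewSet([X[:, perm] for X in b.X]), dims, n_init=1)
        np.testing.assert_allclose(dec_p.C, dec.C[:, perm], atol=1e-6)
        for v in range(2):
            np.testing.assert_allclose(dec_p.S[v], dec.S[v][:, perm], atol=1e-6)

    def test_infeasible_dimensions_rejected(self, rng):
        views = ViewSet([rng.standard_normal((3, 6))])
        with pytest.raises(ValueError):
            fit_isc(views, Dimensions(2, (2,), beta=0.0))

    def test_dimension_invariants(self):
        with pytest.raises(ValueError):
            Dimensions(0, (1,))
        with pytest.raises(ValueError):
            Dimensions(1, (-1,))
        with pytest.raises(ValueError):
            Dimensions(1, (1,), beta=-0.1)
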