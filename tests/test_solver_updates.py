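"""Closed-form ALM block updates: analytic cases, optimality, stationarity."""

import numpy as np
import pytest

import kinelift as kl
from kinelift.camera import make_rotating_camera, project, to_framewise
from kinelift.errors import InvalidInputError
from kinelift.kernels import KernelSpec, kernel_matrix
from kinelift.solver import (
    Hyperparams,
    SolverState,
    dct_basis,
    init_trajectory_dct,
    update_C,
    update_E,
    update_multipliers,
    update_X,
    update_Xhat,
    update_Z,
)


def test_update_Z_analytic_and_limit(rng):
    n = 5
    Z = update_Z(np.zeros((n, n)), np.zeros((n, n)), 2.0)
    np.testing.assert_allclose(Z, 0.5 * np.eye(n), atol=1e-12)
    C = rng.standard_normal((n, n)) * 0.1
    G = rng.standard_normal((n, n)) * 0.1
    big = 1e9
    np.testing.assert_allclose(update_Z(C, G, big), np.eye(n) - C - G / big, atol=1e-7)


def test_update_Z_beats_random_perturbations(rng):
    n = 6
    C = rng.standard_normal((n, n))
    G = rng.standard_normal((n, n))
    mu = 1.7
    Z = update_Z(C, G, mu)
    target = np.eye(n) - C - G / mu

    def obj(A):
        return np.linalg.norm(A, "nuc") + 0.5 * mu * np.sum((A - target) ** 2)

    base = obj(Z)
    for _ in range(200):
        assert obj(Z + 1e-3 * rng.standard_normal(Z.shape)) >= base - 1e-12


def test_update_Xhat_cases_and_optimality(rng):
    X = rng.standard_normal((9, 6))
    G = rng.standard_normal((9, 6))
    mu = 3.0
    np.testing.assert_allclose(update_Xhat(X, G, mu, 0.0), X + G / mu, atol=1e-12)
    # rank-1 input: X^ = max(1 - lambda1/(mu s), 0) * X
    u, v = rng.standard_normal(9), rng.standard_normal(6)
    R1 = np.outer(u, v)
    s = np.linalg.norm(u) * np.linalg.norm(v)
    lam1 = 0.4 * mu * s
    np.testing.assert_allclose(
        update_Xhat(R1, np.zeros_like(R1), mu, lam1), (1 - lam1 / (mu * s)) * R1, atol=1e-10
    )
    lam = 1.3
    Xh = update_Xhat(X, G, mu, lam)

    def obj(A):
        return lam * np.linalg.norm(A, "nuc") + 0.5 * mu * np.sum((A - X - G / mu) ** 2)

    base = obj(Xh)
    for _ in range(200):
        assert obj(Xh + 1e-3 * rng.standard_normal(Xh.shape)) >= base - 1e-12


def test_update_E_cases_and_entrywise_optimality(rng):
    cams = make_rotating_camera(4, 10.0)
    X = rng.standard_normal((9, 4))
    Xs = to_framewise(X)
    W = project(cams, X)
    E = update_E(W, Xs, cams, np.zeros_like(W), 2.0, 1.0)
    np.testing.assert_allclose(E, 0, atol=1e-12)  # noiseless tracks need no error
    W2 = W.copy()
    W2[3, 1] += 10.0  # one gross outlier
    E2 = update_E(W2, Xs, cams, np.zeros_like(W), 1.0, 1.0)  # threshold lambda2/mu = 1
    assert E2[3, 1] == pytest.approx(9.0)
    assert np.count_nonzero(np.abs(E2) > 1e-12) == 1
    # per-entry 1-D grid-search oracle on the subproblem objective
    G = rng.standard_normal(W.shape)
    mu, lam2 = 1.6, 0.8
    E3 = update_E(W2, Xs, cams, G, mu, lam2)
    resid = W2 - project(cams, X) + G / mu
    grid = np.linspace(-12, 12, 4001)
    for i, j in [(0, 0), (3, 1), (5, 2)]:
        vals = lam2 * np.abs(grid) + 0.5 * mu * (grid - resid[i, j]) ** 2
        assert abs(E3[i, j] - grid[np.argmin(vals)]) < 1e-2


def test_update_C_cases_and_stationarity(rng):
    n = 7
    A = rng.standard_normal((n, n))
    K = A @ A.T
    Z = rng.standard_normal((n, n)) * 0.3
    G = rng.standard_normal((n, n)) * 0.3
    mu = 2.2
    np.testing.assert_allclose(
        update_C(K, Z, G, mu, 0.0), np.eye(n) - Z - G / mu, atol=1e-10
    )
    np.testing.assert_allclose(update_C(K, np.eye(n), np.zeros((n, n)), mu, 1.0), 0, atol=1e-10)
    lam3 = 1.4
    C = update_C(K, Z, G, mu, lam3)
    stationarity = 2 * lam3 * K @ C + mu * (C - np.eye(n) + Z) + G
    assert np.linalg.norm(stationarity) < 1e-8


def test_update_multipliers_schedule(small_scene):
    scene = small_scene
    n_frames, n_points = scene.cams.n_frames, scene.skeleton.n_joints
    X = scene.X_gt.copy()
    W = project(scene.cams, X)
    state = SolverState(
        X=X,
        Xhat=X.copy(),
        Z=np.zeros((n_frames, n_frames)),
        C=np.eye(n_frames),
        E=np.zeros((2 * n_frames, n_points)),
        lengths=kl.update_lengths(X, scene.skeleton),
        Gamma1=np.zeros((2 * n_frames, n_points)),
        Gamma2=np.zeros((n_frames, n_frames)),
        Gamma3=np.zeros((3 * n_points, n_frames)),
        mu=1e-3,
    )
    hyper = Hyperparams(rho=1.1, mu0=1e-3)
    # all three constraints exactly satisfied: multipliers untouched, residuals zero
    state = update_multipliers(state, W, scene.cams, hyper)
    assert state.residual_history[-1] == (0.0, 0.0, 0.0)
    assert np.all(state.Gamma1 == 0) and np.all(state.Gamma2 == 0) and np.all(state.Gamma3 == 0)
    # geometric mu schedule and its cap
    for _ in range(9):
        state = update_multipliers(state, W, scene.cams, hyper)
    assert state.mu == pytest.approx(1e-3 * 1.1**10)
    state.mu = hyper.mu_max
    state = update_multipliers(state, W, scene.cams, hyper)
    assert state.mu == hyper.mu_max


def test_update_X_quadratic_case_matches_linear_solve(rng):
    """With lambda3 = lambda4 = 0 the X subproblem is quadratic; the inner
    solver must reach the closed-form normal-equations solution."""
    cams = make_rotating_camera(6, 15.0)
    n_points = 4
    X0 = rng.standard_normal((3 * n_points, 6))
    W = project(cams, rng.standard_normal((3 * n_points, 6)))
    skel = kl.Skeleton(n_points, bones=((0, 1), (1, 2), (2, 3)))
    mu = 2.5
    state = SolverState(
        X=X0,
        Xhat=X0.copy(),
        Z=np.zeros((6, 6)),
        C=np.zeros((6, 6)),
        E=np.zeros((12, n_points)),
        lengths=kl.update_lengths(X0, skel),
        Gamma1=np.zeros((12, n_points)),
        Gamma2=np.zeros((6, 6)),
        Gamma3=np.zeros((3 * n_points, 6)),
        mu=mu,
    )
    hyper = Hyperparams(lambda3=0.0, lambda4=0.0, inner_iter=300)
    X = update_X(state, hyper, cams, skel, KernelSpec("rbf", 1.0), W)
    # normal equations per frame: (I + R_f^T R_f) x = xhat + R_f^T w
    for f in range(6):
        Rf = cams.R[f]
        A = np.eye(3) + Rf.T @ Rf
        for p in range(n_points):
            b = state.Xhat[3 * p : 3 * p + 3, f] + Rf.T @ W[2 * f : 2 * f + 2, p]
            np.testing.assert_allclose(X[3 * p : 3 * p + 3, f], np.linalg.solve(A, b), atol=1e-6)


def test_update_X_never_increases_inner_objective(small_scene):
    from kinelift.solver import _init_state, _x_objective_terms

    scene = small_scene
    W = project(scene.cams, scene.X_gt)
    hyper = Hyperparams()
    state = _init_state(W, scene.cams, scene.skeleton, hyper)
    spec = KernelSpec().resolved(state.X)
    state.mu = 0.5
    state.C = np.eye(scene.cams.n_frames) * 0.3
    f0, _ = _x_objective_terms(state.X, state, hyper, scene.cams, scene.skeleton, spec, W)
    X1 = update_X(state, hyper, scene.cams, scene.skeleton, spec, W)
    f1, _ = _x_objective_terms(X1, state, hyper, scene.cams, scene.skeleton, spec, W)
    assert f1 <= f0 + 1e-12


def test_full_inner_objective_gradient_matches_finite_differences(rng):
    """The assembled X-subproblem gradient (kernel + bones + quadratic terms)
    agrees with central finite differences on a random instance (NP=5, NF=8)."""
    from kinelift.solver import _x_objective_terms

    cams = make_rotating_camera(8, 12.0)
    n_points = 5
    skel = kl.Skeleton(n_points, bones=((0, 1), (1, 2), (2, 3), (2, 4)))
    X = rng.standard_normal((3 * n_points, 8))
    W = project(cams, rng.standard_normal((3 * n_points, 8)))
    spec = KernelSpec("rbf", 1.5)
    hyper = Hyperparams()
    state = SolverState(
        X=X.copy(),
        Xhat=rng.standard_normal(X.shape),
        Z=rng.standard_normal((8, 8)) * 0.2,
        C=rng.standard_normal((8, 8)) * 0.2,
        E=rng.standard_normal((16, n_points)) * 0.1,
        lengths=rng.uniform(0.5, 1.5, size=4),
        Gamma1=rng.standard_normal((16, n_points)) * 0.1,
        Gamma2=np.zeros((8, 8)),
        Gamma3=rng.standard_normal(X.shape) * 0.1,
        mu=1.3,
    )
    val, grad = _x_objective_terms(X, state, hyper, cams, skel, spec, W)
    step = 1e-6
    fd = np.zeros_like(X)
    for idx in np.ndindex(X.shape):
        Xp, Xm = X.copy(), X.copy()
        Xp[idx] += step
        Xm[idx] -= step
        fp, _ = _x_objective_terms(Xp, state, hyper, cams, skel, spec, W)
        fm, _ = _x_objective_terms(Xm, state, hyper, cams, skel, spec, W)
        fd[idx] = (fp - fm) / (2 * step)
    np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-6)


def test_init_trajectory_static_body_and_basis_monotonicity(rng):
    cams = make_rotating_camera(12, 8.0)
    P = rng.standard_normal((3 * 4, 1))
    X = np.repeat(P, 12, axis=1)  # static body
    W = project(cams, X)
    X0 = init_trajectory_dct(W, cams, 1)
    np.testing.assert_allclose(project(cams, X0), W, atol=1e-3)
    W_noisy = W + 0.05 * rng.standard_normal(W.shape)
    resids = []
    for nb in (1, 3, 6, 9, 12):
        Xn = init_trajectory_dct(W_noisy, cams, nb, robust_iters=0)
        resids.append(np.linalg.norm(W_noisy - project(cams, Xn)))
    assert all(a >= b - 1e-8 for a, b in zip(resids, resids[1:]))


def test_dct_basis_orthonormal():
    D = dct_basis(16, 16)
    np.testing.assert_allclose(D.T @ D, np.eye(16), atol=1e-12)


def test_update_guards():
    with pytest.raises(InvalidInputError):
        update_Z(np.zeros((3, 3)), np.zeros((3, 3)), 0.0)
    with pytest.raises(InvalidInputError):
        Hyperparams(rho=0.9)
    with pytest.raises(InvalidInputError):
        Hyperparams(tol=-1)
    with pytest.raises(InvalidInputError):
        Hyperparams(lambda2=-0.1)
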