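"""Augmented-Lagrangian solver for kernelized low-rank motion recovery.

The reconstruction estimates the 3-D motion matrix X from 2-D tracks W and
known orthographic rotations R by minimizing

    ||Z||_* + lambda1 ||X^||_* + lambda2 ||E||_1
    + lambda3 trace((I - Z)^T K(X) (I - Z)) + lambda4 R(X, l)
    s.t.  W = R X# + E,   X^ = X,   C = I - Z,

where Z is the self-expressive affinity over frames, E absorbs gross
observation errors under an L1 penalty, K(X) is the frame kernel, and
R(X, l) is the soft bone-inextensibility penalty with auxiliary lengths l.

The augmented Lagrangian introduces multipliers Gamma1 (reprojection),
Gamma2 (C = I - Z) and Gamma3 (X = X^) and a growing penalty mu. One outer
iteration alternates Z -> X^ -> X -> E -> C -> l, then performs dual ascent
on the multipliers. Z, X^, E have singular-value / element-wise
soft-thresholding closed forms; C and l are linear solves; X is a smooth
nonconvex subproblem handled by a bounded, warm-started quasi-Newton inner
loop with analytic gradients. Convergence of the overall scheme is
empirical, as usual for inexact ALM on nonconvex multi-block problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .camera import CameraTrack, backproject_gradient, project, to_framewise
from .errors import InvalidInputError, SolverDiagnosticError
from .kernels import KernelSpec, kernel_term_gradient, kernel_term_value, kernel_matrix
from .proximal import shrink, svt
from .skeleton import (
    Skeleton,
    bone_lengths_per_frame,
    inext_gradient,
    inext_residual,
    update_lengths,
)

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class Hyperparams:
    """Weights and schedule of the augmented-Lagrangian solver.

    The lambda weights assume tracks scale-normalized to unit RMS (the
    solver does this internally by default). ``lambda5`` only acts in
    marker-less mode, weighting the heightmap likelihood.
    """

    lambda1: float = 1.0  # nuclear norm of the motion matrix
    lambda2: float = 0.15  # L1 observation-error penalty
    lambda3: float = 1.0  # kernel self-expressiveness term
    lambda4: float = 1.0  # soft bone inextensibility
    lambda5: float = 1.0  # heightmap likelihood (marker-less only)
    mu0: float = 1e-3
    rho: float = 1.1
    mu_max: float = 1e8
    tol: float = 1e-6
    max_iter: int = 300
    inner_iter: int = 20
    n_basis: int | None = None  # trajectory-basis size; None -> max(3, NF // 8)
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")
        if not (self.mu0 > 0 and self.mu_max > 0 and self.mu0 < self.mu_max):
            raise InvalidInputError("need 0 < mu0 < mu_max")
        if self.rho <= 1:
            raise InvalidInputError("rho must exceed 1")
        if self.tol <= 0:
            raise InvalidInputError("tol must be positive")
        if self.max_iter < 1 or self.inner_iter < 1:
            raise InvalidInputError("max_iter and inner_iter must be >= 1")


@dataclass
class SolverState:
    """All primal and dual variables of one ALM iteration."""

    X: np.ndarray
    Xhat: np.ndarray
    Z: np.ndarray
    C: np.ndarray
    E: np.ndarray
    lengths: np.ndarray
    Gamma1: np.ndarray
    Gamma2: np.ndarray
    Gamma3: np.ndarray
    mu: float
    iteration: int = 0
    residual_history: list = field(default_factory=list)


@dataclass
class ReconstructionResult:
    """Output of a reconstruction run.

    ``X_est`` is reported in the frame of the input rotations and at the
    scale of the input tracks. ``Z`` is the frame affinity used for
    subspace analysis. ``W_aux`` is only set in marker-less mode (the
    recovered 2-D observations).
    """

    X_est: np.ndarray
    Z: np.ndarray
    E: np.ndarray
    lengths: np.ndarray
    converged: bool
    iterations: int
    residual_history: list
    W_aux: np.ndarray | None = None


# ---------------------------------------------------------------------------
# initialization: trajectory-basis linear fit
# ---------------------------------------------------------------------------


def dct_basis(n_frames: int, n_basis: int) -> np.ndarray:
    """Orthonormal DCT-II basis, columns = the ``n_basis`` lowest frequencies."""
    if not 1 <= n_basis <= n_frames:
        raise InvalidInputError(f"need 1 <= n_basis <= {n_frames}, got {n_basis}")
    f = np.arange(n_frames)[:, None]
    k = np.arange(n_basis)[None, :]
    D = np.cos(np.pi * (f + 0.5) * k / n_frames) * np.sqrt(2.0 / n_frames)
    D[:, 0] = np.sqrt(1.0 / n_frames)
    return D


def init_trajectory_dct(
    W: np.ndarray,
    cams: CameraTrack,
    n_basis: int,
    damping: float = 1e-4,
    robust_iters: int = 10,
) -> np.ndarray:
    """Trajectory-basis initializer: per-joint 3-D paths in a low-frequency basis.

    Each joint's trajectory is constrained to the span of the first
    ``n_basis`` DCT basis vectors over frames, and the coefficients minimize
    the reprojection error ``||W - R X#||_F`` — a linear least-squares
    problem because the rotations are known. Two safeguards on top of the
    plain fit:

    * a small Tikhonov damping (relative to the unit top singular value of
      the design matrix) keeps nearly-unobservable depth directions from
      exploding — those directions are resolved by the solver's priors, not
      by the initializer;
    * ``robust_iters`` rounds of iteratively-reweighted least squares with a
      Tukey biweight, so gross track outliers (which the solver's L1 error
      term will absorb) do not poison the starting point. Set to 0 for the
      plain least-squares fit.
    """
    W = np.asarray(W, dtype=float)
    n_frames = cams.n_frames
    if W.ndim != 2 or W.shape[0] != 2 * n_frames:
        raise InvalidInputError(f"W must be ({2 * n_frames}, NP), got {W.shape}")
    D = dct_basis(n_frames, n_basis)
    # B[2f:2f+2, 3k:3k+3] = D[f, k] * R_f  ->  (2 NF, 3 n_basis)
    B = (D[:, None, :, None] * cams.R[:, :, None, :]).reshape(2 * n_frames, 3 * n_basis)
    rank = np.linalg.matrix_rank(B)
    if rank < 3 * n_basis:
        logger.warning(
            "trajectory initializer design matrix is rank deficient (%d < %d); "
            "the damped least-squares solution is used",
            rank,
            3 * n_basis,
        )
    reg = damping * np.eye(3 * n_basis)
    A = np.linalg.solve(B.T @ B + reg, B.T @ W)
    w_rms = float(np.sqrt(np.mean(W**2)))
    for _ in range(robust_iters):
        resid = W - B @ A
        # robust scale: MAD floored at a fraction of the data RMS, so that
        # basis-truncation mismatch on clean data is never treated as outlying
        # and a near-exact fit cannot zero out every weight
        scale = max(1.4826 * float(np.median(np.abs(resid))), 0.05 * w_rms, 1e-12)
        r = np.abs(resid) / (4.685 * scale)
        weights = np.where(r <= 1.0, (1.0 - r**2) ** 2, 0.0)
        A = np.stack(
            [
                np.linalg.solve(B.T @ (weights[:, p, None] * B) + reg, B.T @ (weights[:, p] * W[:, p]))
                for p in range(W.shape[1])
            ],
            axis=1,
        )
    n_points = W.shape[1]
    # A rows are grouped (basis k) x (coordinate); reorder to frames x coords x joints
    T = (D @ A.reshape(n_basis, 3 * n_points)).reshape(n_frames, 3, n_points)
    return T.transpose(2, 1, 0).reshape(3 * n_points, n_frames)


# ---------------------------------------------------------------------------
# closed-form block updates
# ---------------------------------------------------------------------------


def update_Z(C: np.ndarray, Gamma2: np.ndarray, mu: float) -> np.ndarray:
    """Affinity update: singular-value shrinkage of ``I - C - Gamma2/mu`` at 1/mu."""
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    n = C.shape[0]
    return svt(np.eye(n) - C - Gamma2 / mu, 1.0 / mu)


def update_Xhat(X: np.ndarray, Gamma3: np.ndarray, mu: float, lambda1: float) -> np.ndarray:
    """Low-rank shape proxy: singular-value shrinkage of ``X + Gamma3/mu`` at lambda1/mu."""
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    return svt(X + Gamma3 / mu, lambda1 / mu)


def update_E(
    W: np.ndarray, X_sharp: np.ndarray, cams: CameraTrack, Gamma1: np.ndarray, mu: float, lambda2: float
) -> np.ndarray:
    """Sparse-error update: element-wise shrinkage of the reprojection residual."""
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    n_frames = cams.n_frames
    frames = X_sharp.reshape(n_frames, 3, X_sharp.shape[1])
    RX = np.einsum("fij,fjp->fip", cams.R, frames).reshape(2 * n_frames, X_sharp.shape[1])
    return shrink(W - RX + Gamma1 / mu, lambda2 / mu)


def update_C(K: np.ndarray, Z: np.ndarray, Gamma2: np.ndarray, mu: float, lambda3: float) -> np.ndarray:
    """Solve ``(2 lambda3 K + mu I) C = mu (I - Z) - Gamma2`` for C."""
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    n = K.shape[0]
    A = 2.0 * lambda3 * K + mu * np.eye(n)
    rhs = mu * (np.eye(n) - Z) - Gamma2
    cond = np.linalg.cond(A)
    if cond > _COND_LIMIT:
        logger.warning("C-update system is ill-conditioned (cond=%.2e); using least squares", cond)
        return np.linalg.lstsq(A, rhs, rcond=None)[0]
    return np.linalg.solve(A, rhs)


# ---------------------------------------------------------------------------
# the smooth X subproblem
# ---------------------------------------------------------------------------


def _x_objective_terms(
    X: np.ndarray,
    state: SolverState,
    hyper: Hyperparams,
    cams: CameraTrack,
    skel: Skeleton,
    spec: KernelSpec,
    W: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Value and gradient of the X-subproblem objective (motion layout)."""
    mu = state.mu
    val = 0.0
    grad = np.zeros_like(X)
    C = state.C
    if hyper.lambda3 > 0:
        K = kernel_matrix(X, spec)
        val += hyper.lambda3 * kernel_term_value(K, C)
        grad += hyper.lambda3 * kernel_term_gradient(X, C, spec)
    if hyper.lambda4 > 0:
        val += hyper.lambda4 * inext_residual(X, state.lengths, skel)
        grad += hyper.lambda4 * inext_gradient(X, state.lengths, skel)
    # proximity to the low-rank proxy
    P = X - state.Xhat + state.Gamma3 / mu
    val += 0.5 * mu * float(np.sum(P * P))
    grad += mu * P
    # reprojection
    Q = W - project(cams, X) - state.E + state.Gamma1 / mu
    val += 0.5 * mu * float(np.sum(Q * Q))
    grad -= mu * backproject_gradient(cams, Q)
    return val, grad


def update_X(
    state: SolverState,
    hyper: Hyperparams,
    cams: CameraTrack,
    skel: Skeleton,
    spec: KernelSpec,
    W: np.ndarray,
) -> np.ndarray:
    """Inner quasi-Newton solve of the smooth X subproblem.

    Warm-started at the current X; the returned iterate never has a larger
    subproblem objective than the warm start (falls back to it otherwise).
    """
    X0 = state.X
    shape = X0.shape
    if hyper.lambda4 > 0:
        X0 = _nudge_coincident_joints(X0, skel)

    def fun(x):
        v, g = _x_objective_terms(x.reshape(shape), state, hyper, cams, skel, spec, W)
        return v, g.ravel()

    f0, _ = fun(X0.ravel())
    if not np.isfinite(f0):
        raise SolverDiagnosticError("X subproblem objective is non-finite at the warm start", state)
    res = minimize(fun, X0.ravel(), jac=True, method="L-BFGS-B", options={"maxiter": hyper.inner_iter})
    if not np.isfinite(res.fun) or res.fun > f0:
        return X0
    return res.x.reshape(shape)


def _nudge_coincident_joints(X: np.ndarray, skel: Skeleton, eps: float = 1e-6) -> np.ndarray:
    """Perturb coincident connected joints so the bone-length gradient exists."""
    d = bone_lengths_per_frame(X, skel)
    if np.all(d > 1e-9):
        return X
    logger.warning("coincident connected joints detected; perturbing by %g", eps)
    rng = np.random.default_rng(0)
    X = X + eps * rng.standard_normal(X.shape)
    return X


# ---------------------------------------------------------------------------
# dual ascent and the outer loop
# ---------------------------------------------------------------------------


def update_multipliers(
    state: SolverState, W: np.ndarray, cams: CameraTrack, hyper: Hyperparams
) -> SolverState:
    """Dual ascent on the three multipliers plus the penalty schedule.

    Appends the triple of constraint residuals (reprojection, C = I - Z,
    X = X^), each normalized by max(1, ||W||_F), to the residual history.
    """
    mu = state.mu
    r1 = W - project(cams, state.X) - state.E
    n = state.Z.shape[0]
    r2 = state.C - np.eye(n) + state.Z
    r3 = state.X - state.Xhat
    state.Gamma1 = state.Gamma1 + mu * r1
    state.Gamma2 = state.Gamma2 + mu * r2
    state.Gamma3 = state.Gamma3 + mu * r3
    state.mu = min(hyper.rho * mu, hyper.mu_max)
    scale = max(1.0, float(np.linalg.norm(W)))
    state.residual_history.append(
        (
            float(np.linalg.norm(r1)) / scale,
            float(np.linalg.norm(r2)) / scale,
            float(np.linalg.norm(r3)) / scale,
        )
    )
    return state


def _default_n_basis(n_frames: int, n_basis: int | None) -> int:
    if n_basis is not None:
        return n_basis
    return min(n_frames, max(3, n_frames // 8))


def _init_state(W: np.ndarray, cams: CameraTrack, skel: Skeleton, hyper: Hyperparams) -> SolverState:
    n_frames = cams.n_frames
    n_points = W.shape[1]
    X0 = init_trajectory_dct(W, cams, _default_n_basis(n_frames, hyper.n_basis))
    zeros_nf = np.zeros((n_frames, n_frames))
    return SolverState(
        X=X0,
        Xhat=X0.copy(),
        Z=zeros_nf.copy(),
        C=zeros_nf.copy(),
        E=np.zeros((2 * n_frames, n_points)),
        lengths=update_lengths(X0, skel),
        Gamma1=np.zeros((2 * n_frames, n_points)),
        Gamma2=zeros_nf.copy(),
        Gamma3=np.zeros((3 * n_points, n_frames)),
        mu=hyper.mu0,
    )


def _check_finite_state(state: SolverState) -> None:
    for name in ("X", "Xhat", "Z", "C", "E", "Gamma1", "Gamma2", "Gamma3"):
        if not np.all(np.isfinite(getattr(state, name))):
            raise SolverDiagnosticError(f"solver variable {name} became non-finite", state)


def alm_loop(
    W: np.ndarray,
    cams: CameraTrack,
    skel: Skeleton,
    hyper: Hyperparams,
    spec: KernelSpec,
    observation_update=None,
) -> tuple[SolverState, np.ndarray, bool]:
    """Core alternating loop shared by the marker-based and marker-less modes.

    ``observation_update(state, W) -> W'`` (when given) replaces the
    observations after the E step of every iteration — the marker-less mode
    uses it to re-localize the 2-D joints on the heightmaps. Returns the
    final state, the final observations and the convergence flag.
    """
    W = np.asarray(W, dtype=float)
    state = _init_state(W, cams, skel, hyper)
    spec = spec.resolved(state.X)  # freeze median-heuristic bandwidth at X0
    converged = False
    for it in range(hyper.max_iter):
        state.iteration = it + 1
        state.Z = update_Z(state.C, state.Gamma2, state.mu)
        state.Xhat = update_Xhat(state.X, state.Gamma3, state.mu, hyper.lambda1)
        state.X = update_X(state, hyper, cams, skel, spec, W)
        X_sharp = to_framewise(state.X)
        state.E = update_E(W, X_sharp, cams, state.Gamma1, state.mu, hyper.lambda2)
        if observation_update is not None:
            W = observation_update(state, X_sharp)
        K = kernel_matrix(state.X, spec)
        state.C = update_C(K, state.Z, state.Gamma2, state.mu, hyper.lambda3)
        state.lengths = update_lengths(state.X, skel)
        state = update_multipliers(state, W, cams, hyper)
        _check_finite_state(state)
        if max(state.residual_history[-1]) < hyper.tol:
            converged = True
            break
    return state, W, converged


def center_tracks(W: np.ndarray) -> np.ndarray:
    """Remove the per-frame 2-D centroid (orthographic translation) from W.

    The centroid is the per-frame median over joints rather than the mean:
    under the L1 observation model a single gross outlier must not shift the
    reference frame of every other joint in that frame.
    """
    W = np.asarray(W, dtype=float)
    return W - np.median(W, axis=1, keepdims=True)


def reconstruct(
    W: np.ndarray,
    cams: CameraTrack,
    skel: Skeleton,
    hyper: Hyperparams | None = None,
    spec: KernelSpec | None = None,
    center: bool = True,
    normalize_scale: bool = True,
) -> ReconstructionResult:
    """Recover 3-D joint motion from 2-D tracks and known camera rotations.

    Parameters
    ----------
    W : (2*NF, NP) array
        Image tracks; rows 2f, 2f+1 hold the two coordinates of frame f.
    cams : CameraTrack
        Known per-frame orthographic camera matrices.
    skel : Skeleton
        Bone connectivity for the inextensibility prior.
    hyper, spec
        Solver weights/schedule and kernel choice (defaults used if None).
    center : bool
        Remove the per-frame 2-D centroid before solving (orthographic
        translation is unobservable and assumed removed).
    normalize_scale : bool
        Scale W to unit RMS internally so the default lambda weights apply;
        the output is reported back at the input scale.
    """
    hyper = hyper or Hyperparams()
    spec = spec or KernelSpec()
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise InvalidInputError("tracks contain non-finite entries")
    if center:
        W = center_tracks(W)
    scale = 1.0
    if normalize_scale:
        rms = float(np.sqrt(np.mean(W**2)))
        if rms > 0:
            scale = rms
    state, _, converged = alm_loop(W / scale, cams, skel, hyper, spec)
    X_est = state.X * scale
    if center:
        # report the body centred at the origin in every frame (orthographic
        # translation is unobservable; this is the package's output convention)
        from .camera import from_joints_array, joints_array

        pts = joints_array(X_est)
        X_est = from_joints_array(pts - pts.mean(axis=1, keepdims=True))
    return ReconstructionResult(
        X_est=X_est,
        Z=state.Z,
        E=state.E * scale,
        lengths=state.lengths * scale,
        converged=converged,
        iterations=state.iteration,
        residual_history=list(state.residual_history),
    )
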