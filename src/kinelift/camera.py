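"""Orthographic camera model and motion-matrix layouts.

Two rearrangements of the same 3-D joint coordinates are used throughout:

* the *point-wise* matrix ``X`` of shape ``(3*NP, NF)`` whose column ``f``
  stacks the NP joint positions of frame ``f`` (``X[3p:3p+3, f]`` is joint
  ``p`` at frame ``f``), and
* the *frame-wise* matrix ``X#`` of shape ``(3*NF, NP)`` whose row-block
  ``f`` holds frame ``f``'s joints as columns.

With ``R`` the block-diagonal stack of per-frame 2x3 orthographic camera
matrices, the projection of the sequence is ``W = R @ X#`` of shape
``(2*NF, NP)``: rows ``2f, 2f+1`` are the two image coordinates of all
joints at frame ``f``.

Camera rotations are an *input* to every routine in this package; they are
never estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class CameraTrack:
    """A sequence of 2x3 orthographic camera matrices, one per frame.

    Attributes
    ----------
    R : (NF, 2, 3) array
        Per-frame camera matrices; each must have orthonormal rows.
    """

    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 3 or R.shape[1:] != (2, 3) or R.shape[0] < 1:
            raise InvalidInputError(f"camera track must have shape (NF, 2, 3), got {R.shape}")
        if not np.all(np.isfinite(R)):
            raise InvalidInputError("camera matrices contain non-finite entries")
        gram = np.einsum("fij,fkj->fik", R, R)
        if not np.allclose(gram, np.eye(2), atol=_ORTHO_TOL):
            raise InvalidInputError("camera matrices must have orthonormal rows")
        object.__setattr__(self, "R", R)

    @property
    def n_frames(self) -> int:
        return self.R.shape[0]

    def block_diagonal(self) -> np.ndarray:
        """Dense (2*NF, 3*NF) block-diagonal assembly of the camera matrices."""
        nf = self.n_frames
        out = np.zeros((2 * nf, 3 * nf))
        for f in range(nf):
            out[2 * f : 2 * f + 2, 3 * f : 3 * f + 3] = self.R[f]
        return out


def _as_pointwise(X: np.ndarray) -> tuple[np.ndarray, int, int]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] % 3 != 0 or X.shape[0] == 0:
        raise InvalidInputError(f"point-wise motion matrix must be (3*NP, NF), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("motion matrix contains non-finite entries")
    return X, X.shape[0] // 3, X.shape[1]


def to_framewise(X: np.ndarray) -> np.ndarray:
    """Rearrange a (3*NP, NF) motion matrix into its (3*NF, NP) frame-wise form."""
    X, n_points, n_frames = _as_pointwise(X)
    return X.reshape(n_points, 3, n_frames).transpose(2, 1, 0).reshape(3 * n_frames, n_points)


def to_pointwise(X_sharp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_framewise`."""
    Xs = np.asarray(X_sharp, dtype=float)
    if Xs.ndim != 2 or Xs.shape[0] % 3 != 0 or Xs.shape[0] == 0:
        raise InvalidInputError(f"frame-wise motion matrix must be (3*NF, NP), got {Xs.shape}")
    n_frames, n_points = Xs.shape[0] // 3, Xs.shape[1]
    return Xs.reshape(n_frames, 3, n_points).transpose(2, 1, 0).reshape(3 * n_points, n_frames)


def joints_array(X: np.ndarray) -> np.ndarray:
    """View a (3*NP, NF) motion matrix as an (NF, NP, 3) array of joint positions."""
    X, n_points, n_frames = _as_pointwise(X)
    return X.reshape(n_points, 3, n_frames).transpose(2, 0, 1)


def from_joints_array(P: np.ndarray) -> np.ndarray:
    """Inverse of :func:`joints_array`: (NF, NP, 3) -> (3*NP, NF)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 3 or P.shape[2] != 3:
        raise InvalidInputError(f"expected (NF, NP, 3) joint array, got {P.shape}")
    return P.transpose(1, 2, 0).reshape(3 * P.shape[1], P.shape[0])


def project(cams: CameraTrack, X: np.ndarray) -> np.ndarray:
    """Orthographic projection ``W = R @ X#`` of shape (2*NF, NP)."""
    X, n_points, n_frames = _as_pointwise(X)
    if cams.n_frames != n_frames:
        raise InvalidInputError(
            f"camera track has {cams.n_frames} frames but motion has {n_frames}"
        )
    frames = X.reshape(n_points, 3, n_frames).transpose(2, 1, 0)  # (NF, 3, NP)
    return np.einsum("fij,fjp->fip", cams.R, frames).reshape(2 * n_frames, n_points)


def backproject_gradient(cams: CameraTrack, Q: np.ndarray) -> np.ndarray:
    """Map a (2*NF, NP) image-space matrix Q to motion-matrix layout via R^T.

    Returns the (3*NP, NF) matrix G with ``G[:, f]`` assembled from
    ``R_f^T @ Q[2f:2f+2, :]``; this is the adjoint of :func:`project` and
    hence the building block of reprojection-term gradients.
    """
    Q = np.asarray(Q, dtype=float)
    n_frames = cams.n_frames
    if Q.ndim != 2 or Q.shape[0] != 2 * n_frames:
        raise InvalidInputError(f"expected ({2 * n_frames}, NP) matrix, got {Q.shape}")
    Qf = Q.reshape(n_frames, 2, Q.shape[1])
    G = np.einsum("fij,fip->fjp", cams.R, Qf)  # (NF, 3, NP)
    return G.transpose(2, 1, 0).reshape(3 * Q.shape[1], n_frames)


def make_rotating_camera(n_frames: int, degrees_per_frame: float) -> CameraTrack:
    """Camera orbiting the vertical (y) axis while pointing at the origin.

    Frame ``f`` (0-based) views the scene after a rotation of
    ``f * degrees_per_frame`` degrees about y; the returned 2x3 matrices are
    the first two rows of that rotation.
    """
    if n_frames < 1:
        raise InvalidInputError("n_frames must be >= 1")
    theta = np.deg2rad(degrees_per_frame) * np.arange(n_frames)
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros((n_frames, 2, 3))
    R[:, 0, 0] = c
    R[:, 0, 2] = s
    R[:, 1, 1] = 1.0
    return CameraTrack(R)
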