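"""Frame-wise kernel matrix and the self-expressiveness regularizer.

The nonlinear union-of-subspaces prior is expressed through a kernel on the
frame columns ``x_i`` of the motion matrix: ``K_ij = k(x_i, x_j)``. The
regularizer value is ``trace(C^T K(X) C)`` with ``C = I - Z``; because ``K``
depends on ``X``, its gradient with respect to ``X`` includes the chain rule
through the kernel (verified against finite differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

_KINDS = ("rbf", "linear")


@dataclass(frozen=True)
class KernelSpec:
    """Choice of kernel on frame columns.

    Parameters
    ----------
    kind : {"rbf", "linear"}
        ``rbf`` is the default Gaussian kernel
        ``exp(-||x_i - x_j||^2 / (2 sigma^2))``; ``linear`` gives
        ``K = X^T X`` and recovers the linear low-rank-representation
        behaviour (useful as an ablation).
    bandwidth : float or "median"
        RBF bandwidth sigma. ``"median"`` resolves it to the median of the
        pairwise distances between frame columns.
    """

    kind: str = "rbf"
    bandwidth: float | str = "median"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown kernel kind {self.kind!r}; choose from {_KINDS}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise InvalidInputError(f"bandwidth must be positive or 'median', got {self.bandwidth!r}")
        elif not (np.isfinite(self.bandwidth) and self.bandwidth > 0):
            raise InvalidInputError(f"bandwidth must be positive, got {self.bandwidth!r}")

    def resolved(self, X: np.ndarray) -> "KernelSpec":
        """Return a spec with a numeric bandwidth (median heuristic applied on X)."""
        if self.kind != "rbf" or not isinstance(self.bandwidth, str):
            return self
        return KernelSpec("rbf", median_bandwidth(X))


def median_bandwidth(X: np.ndarray) -> float:
    """Median pairwise distance between frame columns of X.

    Falls back to 1.0 (with a logged warning) when the median distance is
    zero, e.g. for a static sequence where all frames coincide.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        logger.warning("median bandwidth undefined for a single frame; using 1.0")
        return 1.0
    med = float(np.median(pdist(X.T)))
    if med <= 0.0:
        logger.warning("median pairwise distance is zero; falling back to bandwidth 1.0")
        return 1.0
    return med


def kernel_matrix(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel Gram matrix on the frame columns of a (3*NP, NF) motion matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InvalidInputError(f"expected a (3*NP, NF) matrix, got shape {X.shape}")
    spec = spec.resolved(X)
    if spec.kind == "linear":
        return X.T @ X
    sq = squareform(pdist(X.T, "sqeuclidean")) if X.shape[1] > 1 else np.zeros((1, 1))
    K = np.exp(-sq / (2.0 * spec.bandwidth**2))
    return 0.5 * (K + K.T)


def kernel_term_value(K: np.ndarray, C: np.ndarray) -> float:
    """``trace(C^T K C)``, the self-expressiveness penalty at C = I - Z."""
    K = np.asarray(K, dtype=float)
    C = np.asarray(C, dtype=float)
    if K.shape != C.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InvalidInputError(f"K and C must be equal square matrices, got {K.shape} and {C.shape}")
    return float(np.einsum("ij,ij->", C, K @ C))


def kernel_term_gradient(X: np.ndarray, C: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gradient of ``trace(C^T K(X) C)`` with respect to X.

    With ``M = C C^T`` (symmetric) the value is ``sum_ij M_ij K_ij``. For the
    RBF kernel, column ``i`` of the gradient is
    ``-(2 / sigma^2) * sum_j M_ij K_ij (x_i - x_j)``;
    for the linear kernel it is ``2 X M``.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    n_frames = X.shape[1]
    if C.shape != (n_frames, n_frames):
        raise InvalidInputError(f"C must be ({n_frames}, {n_frames}), got {C.shape}")
    spec = spec.resolved(X)
    M = C @ C.T
    if spec.kind == "linear":
        return 2.0 * X @ M
    if spec.kind != "rbf":  # pragma: no cover - guarded by KernelSpec
        raise NotImplementedError(f"no gradient for kernel kind {spec.kind!r}")
    K = kernel_matrix(X, spec)
    G = M * K  # symmetric
    row_sum = G.sum(axis=1)
    return (-2.0 / spec.bandwidth**2) * (X * row_sum[None, :] - X @ G)
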