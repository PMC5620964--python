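"""Reconstruction-error metrics and subspace-clustering analysis.

The scale-free mean error normalizes per-point Euclidean errors by the
ground-truth shape's average coordinate spread:

    e_mean = (1 / (sigma NF NP)) sum_{f,p} e_{fp},
    sigma  = (1 / 3NF) sum_f (sigma_fx + sigma_fy + sigma_fz),

where ``sigma_f*`` are the per-frame standard deviations of the ground-truth
coordinates and ``e_{fp}`` the per-joint position errors. The median error
is reported as ``median(e_fp) / sigma`` (the same normalization, midpoint
convention at even counts).

Monocular orthographic reconstruction carries a depth-reflection ambiguity:
the metric is evaluated with and without a whole-sequence z-flip of the
estimate and the smaller value is reported, together with the flip used.
No Procrustes alignment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import SpectralClustering

from .camera import joints_array
from .errors import InvalidInputError


@dataclass
class ErrorReport:
    e_mean: float
    e_med: float
    e_fp: np.ndarray  # (NF, NP) per-joint Euclidean errors (unnormalized)
    sigma: float
    flip_used: int  # +1 (as given) or -1 (depth-reflected estimate)


def _gt_sigma(gt: np.ndarray) -> float:
    """Average per-frame coordinate standard deviation of the ground truth."""
    # gt: (NF, NP, 3); population std per frame and coordinate
    sigma = float(gt.std(axis=1, ddof=0).mean())
    return sigma


def flip_depth(X: np.ndarray) -> np.ndarray:
    """Negate the z coordinate of every joint in a (3*NP, NF) motion matrix."""
    X = np.array(X, dtype=float, copy=True)
    X[2::3, :] *= -1.0
    return X


def emean(X_est: np.ndarray, X_gt: np.ndarray, per_frame_flip: bool = False) -> ErrorReport:
    """Scale-normalized mean (and median) 3-D reconstruction error.

    The whole-sequence depth flip minimizing the mean error is applied and
    recorded; with ``per_frame_flip`` the reflection is resolved per frame
    instead (off by default).
    """
    X_est = np.asarray(X_est, dtype=float)
    X_gt = np.asarray(X_gt, dtype=float)
    if X_est.shape != X_gt.shape:
        raise InvalidInputError(f"shape mismatch: estimate {X_est.shape} vs truth {X_gt.shape}")
    gt = joints_array(X_gt)
    sigma = _gt_sigma(gt)
    if sigma <= 0:
        raise InvalidInputError("degenerate ground truth: zero coordinate spread")

    def per_point_errors(est_matrix):
        est = joints_array(est_matrix)
        return np.linalg.norm(est - gt, axis=2)  # (NF, NP)

    e_plus = per_point_errors(X_est)
    e_minus = per_point_errors(flip_depth(X_est))
    if per_frame_flip:
        take_minus = e_minus.mean(axis=1) < e_plus.mean(axis=1)
        e_fp = np.where(take_minus[:, None], e_minus, e_plus)
        flip = -1 if take_minus.any() else 1
    elif e_minus.mean() < e_plus.mean():
        e_fp, flip = e_minus, -1
    else:
        e_fp, flip = e_plus, 1
    n_frames, n_points = e_fp.shape
    e_mean = float(e_fp.sum() / (sigma * n_frames * n_points))
    return ErrorReport(e_mean=e_mean, e_med=emed(e_fp, sigma), e_fp=e_fp, sigma=sigma, flip_used=flip)


def emed(e_fp: np.ndarray, sigma: float = 1.0) -> float:
    """Median of the per-joint errors, normalized by sigma (midpoint convention)."""
    e_fp = np.asarray(e_fp, dtype=float)
    if e_fp.size == 0:
        raise InvalidInputError("empty error matrix")
    return float(np.median(e_fp) / sigma)


def affinity_to_clusters(Z: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of frames from a self-expressive affinity matrix.

    The (possibly asymmetric, signed) coefficient matrix Z is symmetrized as
    ``A = (|Z| + |Z^T|) / 2`` before normalized spectral clustering. Returns
    0-based frame labels; deterministic given ``seed``.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise InvalidInputError(f"Z must be square, got {Z.shape}")
    n_frames = Z.shape[0]
    if not 1 <= n_clusters <= n_frames:
        raise InvalidInputError(f"need 1 <= n_clusters <= {n_frames}, got {n_clusters}")
    if n_clusters == 1:
        return np.zeros(n_frames, dtype=int)
    A = 0.5 * (np.abs(Z) + np.abs(Z.T))
    model = SpectralClustering(
        n_clusters=n_clusters, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    return model.fit_predict(A)


def temporal_consistency(labels: np.ndarray) -> float:
    """Fraction of consecutive frame pairs sharing a label (1 = one segment)."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size < 2:
        raise InvalidInputError("need at least two frame labels")
    return float(np.mean(labels[1:] == labels[:-1]))


def clustering_accuracy(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    """Best-permutation agreement between two labelings (Hungarian matching)."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise InvalidInputError("label arrays must have equal length")
    t_vals, t_inv = np.unique(labels_true, return_inverse=True)
    p_vals, p_inv = np.unique(labels_pred, return_inverse=True)
    conf = np.zeros((t_vals.size, p_vals.size))
    np.add.at(conf, (t_inv, p_inv), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / labels_true.size)
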