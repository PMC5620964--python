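"""Marker-less reconstruction from per-joint detection heightmaps.

Instead of tracked 2-D joints, each (frame, joint) pair comes with a
nonnegative *heightmap* grid scoring every image location as that joint's
projection (the output of any 2-D joint detector). The observations become
an auxiliary variable W^ that is re-localized inside every outer solver
iteration by minimizing, per (frame, joint) cell independently,

    -lambda5 * h_{f,p}(w) + (mu / 2) * ||w - proj_{f,p}||^2,

where ``proj`` is the current reprojection (plus sparse-error and
multiplier corrections). The coupling W = W^ is enforced by substitution,
keeping the multiplier structure of the marker-based solver unchanged.

Coordinate convention: heightmaps are sampled with bilinear interpolation,
pixel centres at integer (row, col) indices, first grid axis vertical; a
grid origin and isotropic pixel spacing map image coordinates (x, y) to
pixels via ``col = (x - origin_x) / spacing``, ``row = (y - origin_y) /
spacing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .camera import CameraTrack
from .errors import InvalidInputError
from .kernels import KernelSpec
from .solver import Hyperparams, ReconstructionResult, alm_loop
from .skeleton import Skeleton

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeightmapStack:
    """Per-frame, per-joint detector heightmaps with their image mapping.

    Attributes
    ----------
    maps : (NF, NP, H, W) array
        Nonnegative scores.
    origin : (2,) array
        Image (x, y) coordinates of pixel (row 0, col 0)'s centre.
    spacing : float
        Image units per pixel (isotropic).
    """

    maps: np.ndarray
    origin: np.ndarray
    spacing: float

    def __post_init__(self):
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 4:
            raise InvalidInputError(f"heightmaps must be (NF, NP, H, W), got {maps.shape}")
        if np.any(maps < 0) or not np.all(np.isfinite(maps)):
            raise InvalidInputError("heightmap values must be finite and nonnegative")
        if self.spacing <= 0:
            raise InvalidInputError("spacing must be positive")
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(2))

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    @property
    def n_points(self) -> int:
        return self.maps.shape[1]

    def to_pixels(self, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map a (2*NF, NP) track matrix to (row, col) pixel coordinate arrays (NF, NP)."""
        x = W[0::2, :]
        y = W[1::2, :]
        col = (x - self.origin[0]) / self.spacing
        row = (y - self.origin[1]) / self.spacing
        return row, col

    def from_pixels(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_pixels`."""
        n_frames, n_points = row.shape
        W = np.empty((2 * n_frames, n_points))
        W[0::2, :] = col * self.spacing + self.origin[0]
        W[1::2, :] = row * self.spacing + self.origin[1]
        return W

    def argmax_tracks(self) -> np.ndarray:
        """Per-map argmax locations as a (2*NF, NP) track matrix."""
        nf, npts, h, w = self.maps.shape
        flat = self.maps.reshape(nf, npts, h * w).argmax(axis=2)
        return self.from_pixels((flat // w).astype(float), (flat % w).astype(float))


def _bilinear(maps: np.ndarray, row: np.ndarray, col: np.ndarray, clamp_warn: bool = False):
    """Vectorized bilinear values and gradients on a stack of grids.

    ``maps`` is (M, H, W); ``row``/``col`` are (M,) continuous pixel
    coordinates (one query point per grid). Out-of-bounds coordinates are
    clamped to the grid. Returns (value, d/drow, d/dcol), each (M,).
    """
    m, h, w = maps.shape
    if clamp_warn and (np.any(row < 0) or np.any(row > h - 1) or np.any(col < 0) or np.any(col > w - 1)):
        logger.warning("heightmap query outside the grid; coordinates clamped")
    row = np.clip(row, 0.0, h - 1.0)
    col = np.clip(col, 0.0, w - 1.0)
    i0 = np.clip(np.floor(row).astype(int), 0, h - 2) if h > 1 else np.zeros(m, dtype=int)
    j0 = np.clip(np.floor(col).astype(int), 0, w - 2) if w > 1 else np.zeros(m, dtype=int)
    fr = row - i0
    fc = col - j0
    idx = np.arange(m)
    v00 = maps[idx, i0, j0]
    v01 = maps[idx, i0, np.minimum(j0 + 1, w - 1)]
    v10 = maps[idx, np.minimum(i0 + 1, h - 1), j0]
    v11 = maps[idx, np.minimum(i0 + 1, h - 1), np.minimum(j0 + 1, w - 1)]
    val = (1 - fr) * ((1 - fc) * v00 + fc * v01) + fr * ((1 - fc) * v10 + fc * v11)
    d_row = ((1 - fc) * v10 + fc * v11) - ((1 - fc) * v00 + fc * v01)
    d_col = (1 - fr) * (v01 - v00) + fr * (v11 - v10)
    return val, d_row, d_col


def heightmap_score(stack: HeightmapStack, W_aux: np.ndarray) -> float:
    """Detector score H(W^) = -sum of interpolated heightmap values (lower is better)."""
    W_aux = np.asarray(W_aux, dtype=float)
    nf, npts = stack.n_frames, stack.n_points
    if W_aux.shape != (2 * nf, npts):
        raise InvalidInputError(f"expected ({2 * nf}, {npts}) tracks, got {W_aux.shape}")
    row, col = stack.to_pixels(W_aux)
    flat_maps = stack.maps.reshape(nf * npts, *stack.maps.shape[2:])
    val, _, _ = _bilinear(flat_maps, row.ravel(), col.ravel(), clamp_warn=True)
    return float(-val.sum())


def update_What(
    stack: HeightmapStack,
    proj: np.ndarray,
    mu: float,
    lambda5: float,
    n_steps: int = 30,
) -> np.ndarray:
    """Re-localize every 2-D observation on its heightmap.

    ``proj`` is the (2*NF, NP) anchor matrix (reprojection plus error and
    multiplier corrections). Each cell is optimized by projected gradient
    descent with backtracking, seeded both at the anchor and at the
    heightmap argmax; the better of the two results is kept, and the
    composite objective never exceeds its value at the anchor.
    """
    if mu <= 0:
        raise InvalidInputError("mu must be positive")
    nf, npts = stack.n_frames, stack.n_points
    flat_maps = stack.maps.reshape(nf * npts, *stack.maps.shape[2:])
    h, w = flat_maps.shape[1:]
    pr_row, pr_col = stack.to_pixels(proj)
    anchors = np.stack([pr_row.ravel(), pr_col.ravel()], axis=1)  # pixel coords
    # mu acts on image units; convert the quadratic weight to pixel units
    mu_px = mu * stack.spacing**2

    def objective(pts):
        val, d_row, d_col = _bilinear(flat_maps, pts[:, 0], pts[:, 1])
        diff = pts - anchors
        f = -lambda5 * val + 0.5 * mu_px * np.sum(diff**2, axis=1)
        g = np.stack([-lambda5 * d_row, -lambda5 * d_col], axis=1) + mu_px * diff
        return f, g

    def descend(start):
        pts = start.copy()
        f, g = objective(pts)
        step = np.full(pts.shape[0], 1.0 / (mu_px + lambda5 + 1e-12))
        for _ in range(n_steps):
            for _ in range(12):
                cand = pts - step[:, None] * g
                cand[:, 0] = np.clip(cand[:, 0], 0.0, h - 1.0)
                cand[:, 1] = np.clip(cand[:, 1], 0.0, w - 1.0)
                f_new, g_new = objective(cand)
                worse = f_new > f
                if not worse.any():
                    break
                step[worse] *= 0.5
            improved = f_new <= f
            pts[improved] = cand[improved]
            f = np.where(improved, f_new, f)
            g[improved] = g_new[improved]
        return pts, f

    clipped_anchors = anchors.copy()
    clipped_anchors[:, 0] = np.clip(clipped_anchors[:, 0], 0.0, h - 1.0)
    clipped_anchors[:, 1] = np.clip(clipped_anchors[:, 1], 0.0, w - 1.0)
    flat_idx = flat_maps.reshape(len(flat_maps), -1).argmax(axis=1)
    peaks = np.stack([flat_idx // w, flat_idx % w], axis=1).astype(float)
    p1, f1 = descend(clipped_anchors)
    p2, f2 = descend(peaks)
    pts = np.where((f2 < f1)[:, None], p2, p1)
    f_best = np.minimum(f1, f2)
    f_anchor, _ = objective(clipped_anchors)
    keep_anchor = f_anchor < f_best
    pts[keep_anchor] = clipped_anchors[keep_anchor]
    return stack.from_pixels(pts[:, 0].reshape(nf, npts), pts[:, 1].reshape(nf, npts))


def synth_heightmaps(
    W_true: np.ndarray,
    grid: int = 64,
    sigma_px: float = 2.0,
    clutter: float = 0.0,
    seed: int = 0,
) -> HeightmapStack:
    """Synthetic detector heightmaps: a unit Gaussian bump at each true joint.

    Stand-in for a real 2-D joint detector, used to exercise the marker-less
    pipeline offline. With ``clutter > 0``, each map also receives three
    random smooth distractor bumps of peak height ``clutter``. Deterministic
    given ``seed``.
    """
    W_true = np.asarray(W_true, dtype=float)
    if sigma_px <= 0:
        raise InvalidInputError("sigma_px must be positive")
    if not 0 <= clutter < 1:
        raise InvalidInputError("clutter must lie in [0, 1)")
    nf, npts = W_true.shape[0] // 2, W_true.shape[1]
    x = W_true[0::2, :]
    y = W_true[1::2, :]
    margin_px = int(np.ceil(4 * sigma_px)) + 1
    span = max(float(x.max() - x.min()), float(y.max() - y.min()), 1e-9)
    spacing = span / max(grid - 1 - 2 * margin_px, 1)
    origin = np.array(
        [float(x.min()) - margin_px * spacing, float(y.min()) - margin_px * spacing]
    )
    rows = np.arange(grid)[:, None]
    cols = np.arange(grid)[None, :]
    rng = np.random.default_rng(seed)
    maps = np.zeros((nf, npts, grid, grid))
    for f in range(nf):
        for p in range(npts):
            r0 = (y[f, p] - origin[1]) / spacing
            c0 = (x[f, p] - origin[0]) / spacing
            maps[f, p] = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma_px**2))
            if clutter > 0:
                for _ in range(3):
                    rc = rng.uniform(0, grid - 1, size=2)
                    s = rng.uniform(2 * sigma_px, 4 * sigma_px)
                    maps[f, p] += clutter * np.exp(
                        -((rows - rc[0]) ** 2 + (cols - rc[1]) ** 2) / (2 * s**2)
                    )
    return HeightmapStack(maps=maps, origin=origin, spacing=spacing)


def reconstruct_markerless(
    stack: HeightmapStack,
    cams: CameraTrack,
    skel: Skeleton,
    hyper: Hyperparams | None = None,
    spec: KernelSpec | None = None,
    normalize_scale: bool = True,
) -> ReconstructionResult:
    """Marker-less reconstruction: the alternating solver with heightmap data.

    The observation matrix starts at the per-map argmax locations and is
    re-localized each outer iteration (after the sparse-error step) by
    :func:`update_What`. No per-frame centring is applied (the heightmaps
    fix the image frame); with ``normalize_scale`` the image geometry is
    rescaled internally to unit track RMS so the default solver weights
    apply, and results are reported back in the input units.
    """
    hyper = hyper or Hyperparams()
    spec = spec or KernelSpec()
    if stack.n_frames != cams.n_frames:
        raise InvalidInputError(
            f"heightmaps cover {stack.n_frames} frames but cameras cover {cams.n_frames}"
        )
    scale = 1.0
    if normalize_scale:
        rms = float(np.sqrt(np.mean(stack.argmax_tracks() ** 2)))
        if rms > 0:
            scale = rms
    work = HeightmapStack(stack.maps, stack.origin / scale, stack.spacing / scale)
    W0 = work.argmax_tracks()

    def observation_update(state, X_sharp):
        frames = X_sharp.reshape(cams.n_frames, 3, X_sharp.shape[1])
        RX = np.einsum("fij,fjp->fip", cams.R, frames).reshape(2 * cams.n_frames, X_sharp.shape[1])
        proj = RX + state.E - state.Gamma1 / state.mu
        return update_What(work, proj, state.mu, hyper.lambda5)

    state, W_final, converged = alm_loop(
        W0, cams, skel, hyper, spec, observation_update=observation_update
    )
    return ReconstructionResult(
        X_est=state.X * scale,
        Z=state.Z,
        E=state.E * scale,
        lengths=state.lengths * scale,
        converged=converged,
        iterations=state.iteration,
        residual_history=list(state.residual_history),
        W_aux=W_final * scale,
    )
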