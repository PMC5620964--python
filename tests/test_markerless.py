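"""Heightmap interpolation, per-joint relocalization, synthetic detectors."""

import numpy as np
import pytest

import kinelift as kl
from kinelift.errors import InvalidInputError
from kinelift.markerless import HeightmapStack, _bilinear, update_What


def reference_bilinear(grid, row, col):
    """Independent two-loop bilinear interpolator (pixel centres at integers)."""
    h, w = grid.shape
    row = min(max(row, 0.0), h - 1.0)
    col = min(max(col, 0.0), w - 1.0)
    i0, j0 = int(np.floor(row)), int(np.floor(col))
    i0, j0 = min(i0, h - 2), min(j0, w - 2)
    fr, fc = row - i0, col - j0
    return (
        (1 - fr) * (1 - fc) * grid[i0, j0]
        + (1 - fr) * fc * grid[i0, j0 + 1]
        + fr * (1 - fc) * grid[i0 + 1, j0]
        + fr * fc * grid[i0 + 1, j0 + 1]
    )


def gaussian_stack(W_true, **kw):
    return kl.synth_heightmaps(W_true, **kw)


def test_bilinear_matches_reference_at_random_points(rng):
    grid = rng.uniform(0, 1, size=(16, 12))
    maps = np.tile(grid, (50, 1, 1))
    rows = rng.uniform(-1, 16, size=50)
    cols = rng.uniform(-1, 13, size=50)
    vals, _, _ = _bilinear(maps, rows, cols)
    for k in range(50):
        assert vals[k] == pytest.approx(reference_bilinear(grid, rows[k], cols[k]), abs=1e-12)


def test_heightmap_score_trivial_cases():
    zero = HeightmapStack(np.zeros((2, 3, 8, 8)), origin=np.zeros(2), spacing=1.0)
    W = np.ones((4, 3)) * 3.0
    assert kl.heightmap_score(zero, W) == 0.0
    maps = np.zeros((1, 1, 20, 20))
    maps[0, 0, 10, 10] = 1.0
    stack = HeightmapStack(maps, origin=np.zeros(2), spacing=1.0)
    W1 = np.array([[10.0], [10.0]])  # at the peak pixel
    assert kl.heightmap_score(stack, W1) == pytest.approx(-1.0)


def test_heightmap_score_translation_equivariant(rng):
    maps = rng.uniform(0, 1, size=(2, 2, 10, 10))
    W = rng.uniform(2, 7, size=(4, 2))
    a = kl.heightmap_score(HeightmapStack(maps, np.zeros(2), 1.0), W)
    shifted = HeightmapStack(maps, np.array([5.0, -3.0]), 1.0)
    b = kl.heightmap_score(shifted, W + np.array([5.0, -3.0, 5.0, -3.0])[:, None])
    assert a == pytest.approx(b, abs=1e-12)


def test_update_What_limits(rng):
    W_true = rng.uniform(-1, 1, size=(6, 4))
    stack = gaussian_stack(W_true, grid=48, sigma_px=2.0, seed=0)
    proj = W_true + 0.02 * rng.standard_normal(W_true.shape)
    # lambda5 = 0: the anchor wins exactly
    out = update_What(stack, proj, mu=1.0, lambda5=0.0)
    np.testing.assert_allclose(out, proj, atol=1e-12)
    # mu -> 0+: every point locks onto its heightmap mode (the true joint)
    out2 = update_What(stack, proj, mu=1e-9, lambda5=1.0)
    assert np.abs(out2 - W_true).max() < 1.5 * stack.spacing


def test_update_What_flat_heightmap_returns_anchor(rng):
    flat = HeightmapStack(np.ones((2, 2, 8, 8)) * 0.5, np.zeros(2), 1.0)
    proj = rng.uniform(1, 6, size=(4, 2))
    np.testing.assert_allclose(update_What(flat, proj, mu=2.0, lambda5=1.0), proj, atol=1e-9)


def test_update_What_matches_grid_search_oracle(rng):
    """Gaussian bump vs quadratic anchor: the 2-D minimizer found by dense
    grid search agrees within half a pixel."""
    W_true = np.array([[0.0], [0.0]])
    stack = gaussian_stack(W_true, grid=40, sigma_px=3.0, seed=1)
    anchor = W_true + np.array([[4.0], [-3.0]]) * stack.spacing
    mu, lam5 = 0.5 / stack.spacing**2, 1.0
    out = update_What(stack, anchor, mu=mu, lambda5=lam5)
    rows = np.linspace(0, 39, 391)
    cols = np.linspace(0, 39, 391)
    grid = stack.maps[0, 0]
    a_row, a_col = stack.to_pixels(anchor)
    best, best_rc = np.inf, None
    mu_px = mu * stack.spacing**2
    for r in rows:
        for c in cols:
            v = reference_bilinear(grid, r, c)
            f = -lam5 * v + 0.5 * mu_px * ((r - a_row[0, 0]) ** 2 + (c - a_col[0, 0]) ** 2)
            if f < best:
                best, best_rc = f, (r, c)
    o_row, o_col = stack.to_pixels(out)
    assert abs(o_row[0, 0] - best_rc[0]) < 0.5
    assert abs(o_col[0, 0] - best_rc[1]) < 0.5


def test_synth_heightmaps_contract(rng):
    W_true = rng.uniform(-1, 1, size=(10, 5))
    stack = gaussian_stack(W_true, grid=64, sigma_px=2.0, clutter=0.0, seed=4)
    # clutter-free: argmax within one pixel of the truth, peak value ~1
    argmax = stack.argmax_tracks()
    assert np.abs(argmax - W_true).max() <= stack.spacing + 1e-12
    row, col = stack.to_pixels(W_true)
    flat = stack.maps.reshape(-1, 64, 64)
    vals, _, _ = _bilinear(flat, row.ravel(), col.ravel())
    assert vals.min() > 0.9  # interpolation tolerance around the unit peak
    again = gaussian_stack(W_true, grid=64, sigma_px=2.0, clutter=0.0, seed=4)
    np.testing.assert_array_equal(stack.maps, again.maps)
    other = gaussian_stack(W_true, grid=64, sigma_px=2.0, clutter=0.3, seed=5)
    assert np.any(stack.maps != other.maps)


def test_markerless_reconstruction_is_deterministic():
    scene = kl.make_scene(frames=(10, 10), degrees_per_frame=4.0, noise_sd=0.0, seed=1)
    stack = kl.synth_heightmaps(scene.W_clean, grid=32, sigma_px=2.0, seed=1)
    hyper = kl.Hyperparams(max_iter=40)
    r1 = kl.reconstruct_markerless(stack, scene.cams, scene.skeleton, hyper)
    r2 = kl.reconstruct_markerless(stack, scene.cams, scene.skeleton, hyper)
    assert r1.residual_history == r2.residual_history
    np.testing.assert_array_equal(r1.X_est, r2.X_est)
    np.testing.assert_array_equal(r1.W_aux, r2.W_aux)


def test_markerless_large_lambda5_locks_to_modes():
    scene = kl.make_scene(frames=(8, 8), degrees_per_frame=5.0, noise_sd=0.0, seed=2)
    stack = kl.synth_heightmaps(scene.W_clean, grid=32, sigma_px=2.0, seed=2)
    hyper = kl.Hyperparams(lambda5=1e4, max_iter=60)
    res = kl.reconstruct_markerless(stack, scene.cams, scene.skeleton, hyper)
    modes = stack.argmax_tracks()
    rms_px = np.sqrt(np.mean((res.W_aux - modes) ** 2)) / stack.spacing
    assert rms_px < 1.0


def test_heightmap_stack_validation(rng):
    with pytest.raises(InvalidInputError):
        HeightmapStack(np.zeros((2, 8, 8)), np.zeros(2), 1.0)  # missing joint axis
    with pytest.raises(InvalidInputError):
        HeightmapStack(-np.ones((1, 1, 4, 4)), np.zeros(2), 1.0)
    with pytest.raises(InvalidInputError):
        HeightmapStack(np.zeros((1, 1, 4, 4)), np.zeros(2), 0.0)
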