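"""Shared fixtures.

The expensive end-to-end reconstructions are session-scoped and shared
between the acceptance-style tests; unit tests build their own tiny inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

import kinelift as kl


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def rig13():
    return kl.make_skeleton("stick13")


@pytest.fixture(scope="session")
def small_scene():
    """A light 40-frame scene for solver unit tests."""
    return kl.make_scene(frames=(20, 20), degrees_per_frame=3.0, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def benchmark_run():
    """Clean 2-action 120-frame recovery benchmark (seed 7) and its solution."""
    scene = kl.benchmark_scene(seed=7)
    result = kl.reconstruct(scene.W_clean, scene.cams, scene.skeleton)
    return scene, result


@pytest.fixture(scope="session")
def outlier_run():
    """The benchmark scene corrupted with 5% gross outliers, and its solution."""
    scene = kl.benchmark_scene(seed=7, outlier_frac=0.05, outlier_scale=1.0)
    result = kl.reconstruct(scene.W_noisy, scene.cams, scene.skeleton)
    return scene, result


@pytest.fixture(scope="session")
def complex_runs():
    """Complex-motion scenes over 5 seeds, solved with the full method, the
    linear-kernel variant and the no-kernel (lambda3 = 0) ablation."""
    runs = []
    for seed in range(5):
        scene = kl.complex_scene(seed=seed)
        full = kl.reconstruct(scene.W_noisy, scene.cams, scene.skeleton)
        linear = kl.reconstruct(
            scene.W_noisy, scene.cams, scene.skeleton, spec=kl.KernelSpec("linear")
        )
        ablation = kl.reconstruct(
            scene.W_noisy, scene.cams, scene.skeleton, kl.Hyperparams(lambda3=0.0)
        )
        runs.append({"scene": scene, "full": full, "linear": linear, "ablation": ablation})
    return runs


@pytest.fixture(scope="session")
def markerless_run(benchmark_run):
    """Clutter-free synthetic heightmaps on the benchmark scene, solved marker-lessly."""
    scene, _ = benchmark_run
    stack = kl.synth_heightmaps(scene.W_clean, grid=64, sigma_px=2.0, clutter=0.0, seed=7)
    result = kl.reconstruct_markerless(stack, scene.cams, scene.skeleton)
    return scene, stack, result
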