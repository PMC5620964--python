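"""Readers and writers for the package's interchange formats.

All tabular formats are comma-separated UTF-8 text ('.' decimal, LF):

* tracks:    NF rows x 2*NP columns (x1, y1, x2, y2, ...), optional header;
* rotations: NF rows x 6 columns (row-major 2x3 camera matrix);
* motion:    NF rows x 3*NP columns (x, y, z per joint), optional header;
* skeleton:  JSON with ``num_joints``, ``bones`` (0-based pairs), ``names``;
* config:    YAML or JSON, flat keys plus a nested ``kernel`` section;
* heightmaps: one packed little-endian float32 file of shape NF*NP*H*W plus
  a JSON sidecar with the grid geometry (the only binary format).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .kernels import KernelSpec
from .markerless import HeightmapStack
from .solver import Hyperparams

_FLOAT_FMT = "%.17g"


def _read_table(path, n_group: int, what: str) -> tuple[np.ndarray, list[str] | None]:
    try:
        first = pd.read_csv(path, header=None, nrows=1)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise InvalidInputError(f"cannot parse {what} file {path}: {exc}") from exc
    has_header = first.iloc[0].apply(lambda v: isinstance(v, str)).any()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] % n_group != 0:
        raise InvalidInputError(
            f"{what} file {path} has {df.shape[1]} columns; expected a multiple of {n_group}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise InvalidInputError(f"{what} file {path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise InvalidInputError(f"{what} file {path}: non-numeric cell at line {bad[0] + 1}")
    names = list(df.columns) if has_header else None
    return values, names


def read_tracks(path) -> tuple[np.ndarray, list[str] | None]:
    """Read 2-D tracks; returns the (2*NF, NP) matrix and joint names (or None).

    On disk one row is one frame (x, y interleaved per joint); in memory the
    frame occupies two consecutive rows.
    """
    values, names = _read_table(path, 2, "tracks")
    n_frames, n_points = values.shape[0], values.shape[1] // 2
    W = values.reshape(n_frames, n_points, 2).transpose(0, 2, 1).reshape(2 * n_frames, n_points)
    joint_names = None
    if names is not None:
        joint_names = [c[:-2] if c.endswith("_x") else c for c in names[0::2]]
    return W, joint_names


def write_tracks(W: np.ndarray, path, names: list[str] | None = None) -> None:
    W = np.asarray(W, dtype=float)
    n_frames, n_points = W.shape[0] // 2, W.shape[1]
    flat = W.reshape(n_frames, 2, n_points).transpose(0, 2, 1).reshape(n_frames, 2 * n_points)
    header = None
    if names is not None:
        if len(names) != n_points:
            raise InvalidInputError(f"{len(names)} names for {n_points} joints")
        header = [f"{n}_{c}" for n in names for c in ("x", "y")]
    _atomic_csv(flat, path, header)


def read_rotations(path):
    """Read a camera track (NF rows x 6 columns, row-major 2x3)."""
    from .camera import CameraTrack

    values, _ = _read_table(path, 6, "rotations")
    if values.shape[1] != 6:
        raise InvalidInputError(f"rotations file {path} must have exactly 6 columns")
    return CameraTrack(values.reshape(-1, 2, 3))


def write_rotations(cams, path) -> None:
    _atomic_csv(cams.R.reshape(cams.n_frames, 6), path, None)


def read_motion(path) -> np.ndarray:
    """Read a motion CSV (NF rows x 3*NP columns) into the (3*NP, NF) layout."""
    values, _ = _read_table(path, 3, "motion")
    n_frames, n_points = values.shape[0], values.shape[1] // 3
    return values.reshape(n_frames, n_points, 3).transpose(1, 2, 0).reshape(3 * n_points, n_frames)


def write_motion(X: np.ndarray, path) -> None:
    X = np.asarray(X, dtype=float)
    n_points, n_frames = X.shape[0] // 3, X.shape[1]
    flat = X.reshape(n_points, 3, n_frames).transpose(2, 0, 1).reshape(n_frames, 3 * n_points)
    _atomic_csv(flat, path, None)


def read_labels(path) -> np.ndarray:
    values, _ = _read_table(path, 1, "labels")
    return values.ravel().astype(int)


def write_labels(labels: np.ndarray, path) -> None:
    _atomic_csv(np.asarray(labels, dtype=int).reshape(-1, 1), path, None)


def _atomic_csv(values: np.ndarray, path, header: list[str] | None) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df = pd.DataFrame(values, columns=header)
    df.to_csv(tmp, index=False, header=header is not None, float_format=_FLOAT_FMT)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_HYPER_KEYS = (
    "lambda1",
    "lambda2",
    "lambda3",
    "lambda4",
    "lambda5",
    "mu0",
    "rho",
    "mu_max",
    "tol",
    "max_iter",
    "inner_iter",
    "n_basis",
    "seed",
)
_OPTION_KEYS = ("center_tracks", "normalize_scale", "per_frame_flip")
_KERNEL_KEYS = ("kind", "bandwidth")


def default_config() -> dict:
    cfg = asdict(Hyperparams())
    cfg["kernel"] = {"kind": "rbf", "bandwidth": "median"}
    cfg["center_tracks"] = True
    cfg["normalize_scale"] = True
    cfg["per_frame_flip"] = False
    return cfg


def read_config(path=None) -> tuple[Hyperparams, KernelSpec, dict]:
    """Load configuration, filling unset keys with the documented defaults.

    Returns the hyperparameters, the kernel spec and a dict of remaining
    options. Unknown keys and out-of-range values raise a single
    :class:`InvalidInputError` listing every violation.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise InvalidInputError(f"config {path} must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> tuple[Hyperparams, KernelSpec, dict]:
    problems = []
    cfg = default_config()
    for key, value in data.items():
        if key == "kernel":
            if not isinstance(value, dict):
                problems.append("kernel must be a mapping with keys kind, bandwidth")
                continue
            for kk, vv in value.items():
                if kk not in _KERNEL_KEYS:
                    problems.append(f"unknown kernel key {kk!r}")
                else:
                    cfg["kernel"][kk] = vv
        elif key in _HYPER_KEYS or key in _OPTION_KEYS:
            cfg[key] = value
        else:
            problems.append(f"unknown config key {key!r}")
    if problems:
        raise InvalidInputError("invalid configuration: " + "; ".join(problems))
    try:
        hyper = Hyperparams(**{k: cfg[k] for k in _HYPER_KEYS})
        spec = KernelSpec(**cfg["kernel"])
    except InvalidInputError as exc:
        raise InvalidInputError(f"invalid configuration: {exc}") from exc
    options = {k: bool(cfg[k]) for k in _OPTION_KEYS}
    return hyper, spec, options


def config_echo(hyper: Hyperparams, spec: KernelSpec, options: dict) -> dict:
    cfg = asdict(hyper)
    cfg["kernel"] = {"kind": spec.kind, "bandwidth": spec.bandwidth}
    cfg.update(options)
    return cfg


def write_report(report: dict, path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    os.replace(tmp, path)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


# ---------------------------------------------------------------------------
# heightmaps
# ---------------------------------------------------------------------------


def write_heightmaps(stack: HeightmapStack, directory) -> None:
    """Write a heightmap stack as packed float32 plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nf, npts, h, w = stack.maps.shape
    sidecar = {
        "n_frames": nf,
        "n_joints": npts,
        "height": h,
        "width": w,
        "origin": stack.origin.tolist(),
        "spacing": stack.spacing,
        "dtype": "<f4",
    }
    stack.maps.astype("<f4").tofile(directory / "heightmaps.f32")
    with open(directory / "heightmaps.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_heightmaps(directory) -> HeightmapStack:
    directory = Path(directory)
    with open(directory / "heightmaps.json") as fh:
        meta = json.load(fh)
    shape = (meta["n_frames"], meta["n_joints"], meta["height"], meta["width"])
    maps = np.fromfile(directory / "heightmaps.f32", dtype=meta.get("dtype", "<f4"))
    if maps.size != int(np.prod(shape)):
        raise InvalidInputError(
            f"heightmap payload has {maps.size} values; sidecar promises {np.prod(shape)}"
        )
    return HeightmapStack(
        maps=maps.reshape(shape).astype(float),
        origin=np.asarray(meta["origin"], dtype=float),
        spacing=float(meta["spacing"]),
    )
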