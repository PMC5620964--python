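"""Articulated skeletons and the soft bone-inextensibility penalty.

A skeleton is a joint count plus a set of bones (unordered pairs of joint
indices, 0-based). Bone lengths are *auxiliary variables* of the
reconstruction: the penalty

    R(X, l) = sum_f sum_{(p,q) in bones} (||x_{f,p} - x_{f,q}|| - l_{p,q})^2

is minimized jointly over the motion X and the lengths l. For fixed X the
optimal l has a closed form (the per-bone mean length over frames,
:func:`update_lengths`); for fixed l the penalty enters the motion
subproblem through :func:`inext_gradient`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .camera import joints_array
from .errors import DegenerateGeometryError, InvalidInputError

_COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class Skeleton:
    n_joints: int
    bones: tuple[tuple[int, int], ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_joints < 1:
            raise InvalidInputError("skeleton needs at least one joint")
        bones = tuple(tuple(sorted((int(p), int(q)))) for p, q in self.bones)
        seen = set()
        for p, q in bones:
            if p == q:
                raise InvalidInputError(f"bone ({p}, {q}) connects a joint to itself")
            if not (0 <= p < self.n_joints and 0 <= q < self.n_joints):
                raise InvalidInputError(f"bone ({p}, {q}) references a joint outside 0..{self.n_joints - 1}")
            if (p, q) in seen:
                raise InvalidInputError(f"duplicate bone ({p}, {q})")
            seen.add((p, q))
        object.__setattr__(self, "bones", bones)
        if self.names is not None:
            names = tuple(str(n) for n in self.names)
            if len(names) != self.n_joints:
                raise InvalidInputError("names must match the joint count")
            object.__setattr__(self, "names", names)

    @property
    def n_bones(self) -> int:
        return len(self.bones)

    def bone_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bones, dtype=int)
        return b[:, 0], b[:, 1]

    def to_json(self, path) -> None:
        data = {"num_joints": self.n_joints, "bones": [list(b) for b in self.bones]}
        if self.names is not None:
            data["names"] = list(self.names)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Skeleton":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            n_joints=int(data["num_joints"]),
            bones=tuple(tuple(b) for b in data["bones"]),
            names=tuple(data["names"]) if "names" in data else None,
        )


def _bone_vectors(X: np.ndarray, skel: Skeleton) -> np.ndarray:
    """(NF, NB, 3) difference vectors x_{f,p} - x_{f,q} for every bone."""
    pts = joints_array(X)
    if pts.shape[1] != skel.n_joints:
        raise InvalidInputError(f"motion has {pts.shape[1]} joints but skeleton declares {skel.n_joints}")
    p, q = skel.bone_index_arrays()
    return pts[:, p, :] - pts[:, q, :]


def bone_lengths_per_frame(X: np.ndarray, skel: Skeleton) -> np.ndarray:
    """(NF, NB) Euclidean bone lengths of every frame."""
    return np.linalg.norm(_bone_vectors(X, skel), axis=2)


def _check_lengths(lengths: np.ndarray, skel: Skeleton) -> np.ndarray:
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != (skel.n_bones,):
        raise InvalidInputError(f"expected {skel.n_bones} bone lengths, got shape {lengths.shape}")
    if not np.all(np.isfinite(lengths)):
        raise InvalidInputError("bone lengths must be finite")
    return lengths


def inext_residual(X: np.ndarray, lengths: np.ndarray, skel: Skeleton) -> float:
    """Soft-inextensibility penalty R(X, l); zero iff every bone keeps its nominal length."""
    lengths = _check_lengths(lengths, skel)
    d = bone_lengths_per_frame(X, skel)
    return float(np.sum((d - lengths[None, :]) ** 2))


def inext_gradient(X: np.ndarray, lengths: np.ndarray, skel: Skeleton) -> np.ndarray:
    """Gradient of R(X, l) with respect to X, in (3*NP, NF) layout.

    Undefined (raises :class:`DegenerateGeometryError`) when two connected
    joints coincide in some frame.
    """
    lengths = _check_lengths(lengths, skel)
    vec = _bone_vectors(X, skel)  # (NF, NB, 3)
    d = np.linalg.norm(vec, axis=2)  # (NF, NB)
    if np.any(d <= _COINCIDENT_TOL):
        raise DegenerateGeometryError("connected joints coincide; bone-length gradient undefined")
    coef = 2.0 * (d - lengths[None, :]) / d  # (NF, NB)
    contrib = coef[:, :, None] * vec  # (NF, NB, 3)
    n_frames, n_points = vec.shape[0], skel.n_joints
    grad = np.zeros((n_frames, n_points, 3))
    p, q = skel.bone_index_arrays()
    np.add.at(grad, (slice(None), p), contrib)
    np.add.at(grad, (slice(None), q), -contrib)
    return grad.transpose(1, 2, 0).reshape(3 * n_points, n_frames)


def update_lengths(X: np.ndarray, skel: Skeleton) -> np.ndarray:
    """Closed-form bone-length update: per-bone mean length over frames.

    Minimizes R(X, l) over l for fixed X (the stationarity condition of the
    quadratic-in-l penalty).
    """
    return bone_lengths_per_frame(X, skel).mean(axis=0)
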