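"""Core data model: point sequences, rigid transforms, mappings, and RMSD.

The package-wide convention is that a :class:`RigidTransform` moves the
second structure (Q) onto the first (P): the residual of a matched pair
``(i, j)`` is ``R @ q_j + t - p_i``.  All indices are 0-based internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PointSequence",
    "RigidTransform",
    "Mapping",
    "AlignmentResult",
    "superpose",
    "rmsd_fixed",
    "apply_transform",
    "rotation_from_correlation",
]

#: Default cap on the distance between consecutive C-alpha atoms, in Angstrom.
DEFAULT_BOND_CAP = 3.8

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for invalid geometric inputs."""


@dataclass(frozen=True)
class PointSequence:
    """An ordered sequence of 3D points (a C-alpha trace or a test point set).

    Parameters
    ----------
    coords
        Array of shape ``(n, 3)``; copied and stored as float64.  Integer
        coordinates up to 2**53 are represented exactly.
    name
        Free-text label.
    integral
        If true, every coordinate must be an integer.
    protein_mode
        If true, consecutive points must be within ``bond_cap`` of each other.
    bond_cap
        Consecutive-distance cap used when ``protein_mode`` is set.
    """

    coords: np.ndarray
    name: str = ""
    integral: bool = False
    protein_mode: bool = False
    bond_cap: float = DEFAULT_BOND_CAP

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise GeometryError(f"coords must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise GeometryError("a point sequence needs at least one point")
        if not np.all(np.isfinite(arr)):
            raise GeometryError("non-finite coordinates")
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)
        if self.integral and not np.array_equal(arr, np.round(arr)):
            raise GeometryError("integral flag set but coordinates are not integers")
        if self.protein_mode and len(arr) > 1:
            steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
            if steps.max() > self.bond_cap + 1e-9:
                raise GeometryError(
                    f"consecutive-point distance {steps.max():.6g} exceeds "
                    f"cap {self.bond_cap:.6g}"
                )

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def c_max(self) -> float:
        """Largest absolute coordinate value."""
        return float(np.abs(self.coords).max())

    def subset(self, indices: Sequence[int]) -> np.ndarray:
        return self.coords[np.asarray(indices, dtype=int)]

    def with_coords(self, coords: np.ndarray, **kwargs) -> "PointSequence":
        return replace(self, coords=coords, **kwargs)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.ascontiguousarray(np.asarray(self.rotation, dtype=float))
        tra = np.ascontiguousarray(np.asarray(self.translation, dtype=float))
        if rot.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if tra.shape != (3,):
            raise GeometryError("translation must be a 3-vector")
        if not np.all(np.isfinite(rot)) or not np.all(np.isfinite(tra)):
            raise GeometryError("non-finite transform")
        if np.abs(rot.T @ rot - np.eye(3)).max() > 1e-8:
            raise GeometryError("rotation is not orthonormal")
        if abs(np.linalg.det(rot) - 1.0) > 1e-8:
            raise GeometryError("rotation must be proper (det = +1)")
        rot.setflags(write=False)
        tra.setflags(write=False)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_flat(cls, values: Sequence[float]) -> "RigidTransform":
        """Build from 12 numbers: row-major rotation followed by translation."""
        vals = np.asarray(list(values), dtype=float)
        if vals.shape != (12,):
            raise GeometryError("expected 12 numbers (row-major R, then t)")
        return cls(vals[:9].reshape(3, 3), vals[9:])

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.rotation.ravel(), self.translation])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


@dataclass(frozen=True)
class Mapping:
    """A partial bijection between two point sequences.

    ``pairs[k] = (i, j)`` matches point ``i`` of P with point ``j`` of Q
    (0-based).  When ``sequential`` both index columns must strictly
    increase along the list.
    """

    pairs: tuple[tuple[int, int], ...]
    sequential: bool = True

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        i_idx = [p[0] for p in pairs]
        j_idx = [p[1] for p in pairs]
        if len(set(i_idx)) != len(i_idx) or len(set(j_idx)) != len(j_idx):
            raise GeometryError("mapping indices must be distinct on each side")
        if any(i < 0 for i in i_idx) or any(j < 0 for j in j_idx):
            raise GeometryError("mapping indices must be non-negative")
        if self.sequential and len(pairs) > 1:
            if any(a >= b for a, b in zip(i_idx, i_idx[1:])) or any(
                a >= b for a, b in zip(j_idx, j_idx[1:])
            ):
                raise GeometryError("sequential mapping must strictly increase")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, n: int) -> "Mapping":
        return cls(tuple((i, i) for i in range(n)))

    @classmethod
    def from_arrays(cls, i_idx: Iterable[int], j_idx: Iterable[int],
                    sequential: bool = True) -> "Mapping":
        return cls(tuple(zip(i_idx, j_idx)), sequential=sequential)

    @property
    def i_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def j_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    def validate_against(self, P: PointSequence, Q: PointSequence) -> None:
        if len(self.pairs) == 0:
            return
        if self.i_indices.max() >= len(P) or self.j_indices.max() >= len(Q):
            raise GeometryError("mapping index out of range")


@dataclass(frozen=True)
class AlignmentResult:
    """An alignment: a mapping, a transform moving Q onto P, and its RMSD."""

    mapping: Mapping
    transform: RigidTransform
    rmsd: float
    size: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size != len(self.mapping):
            raise GeometryError("size must equal the number of mapped pairs")
        if self.rmsd < 0:
            raise GeometryError("rmsd must be non-negative")


def _mapped_coords(P: PointSequence, Q: PointSequence,
                   mapping: Mapping) -> tuple[np.ndarray, np.ndarray]:
    if len(mapping) == 0:
        raise GeometryError("empty mapping")
    mapping.validate_against(P, Q)
    return P.subset(mapping.i_indices), Q.subset(mapping.j_indices)


def rotation_from_correlation(M: np.ndarray) -> np.ndarray:
    """Proper rotation maximizing ``trace(R @ M.T)`` for a 3x3 matrix M.

    M is the coordinate correlation matrix ``sum_k p_k q_k^T`` of centered
    matched points; the returned rotation is the Kabsch rotation moving the
    Q-side points onto the P-side ones.  Reflections are removed by flipping
    the sign of the smallest singular direction.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or not np.all(np.isfinite(M)):
        raise GeometryError("M must be a finite 3x3 matrix")
    # trace(R @ M.T) = trace(R @ A) with A = M.T;  A = U S V^T -> R = V U^T
    U, _, Vt = np.linalg.svd(M.T)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # fully degenerate; any proper choice is a maximizer
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(P: PointSequence, Q: PointSequence,
              mapping: Mapping) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of the mapped pairs (Kabsch).

    Returns the transform minimizing ``sum ||R q_j + t - p_i||^2`` over the
    mapped pairs together with the minimized RMSD (normalized by the number
    of mapped pairs).
    """
    p, q = _mapped_coords(P, Q, mapping)
    p_mean = p.mean(axis=0)
    q_mean = q.mean(axis=0)
    pc = p - p_mean
    qc = q - q_mean
    M = pc.T @ qc  # correlation matrix of centered coordinate vectors
    R = rotation_from_correlation(M)
    t = p_mean - R @ q_mean
    resid = qc @ R.T - pc
    rmsd = math.sqrt(max(float((resid * resid).sum()) / len(p), 0.0))
    return RigidTransform(R, t), rmsd


def rmsd_fixed(P: PointSequence, Q: PointSequence, mapping: Mapping,
               T: RigidTransform) -> float:
    """RMSD of the mapped pairs under a fixed (not optimized) transform."""
    p, q = _mapped_coords(P, Q, mapping)
    resid = T.apply(q) - p
    return math.sqrt(float((resid * resid).sum()) / len(p))


def apply_transform(Q: PointSequence, T: RigidTransform) -> PointSequence:
    """Return a transformed copy of the sequence (integral flag dropped)."""
    coords = T.apply(Q.coords)
    return PointSequence(coords, name=Q.name, integral=False,
                         protein_mode=False, bond_cap=Q.bond_cap)
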