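"""Protein-like synthetic instances with known ground truth.

Chains are random walks with a capped step length (the C-alpha consecutive
distance cap); instances for the exact algorithms use integer coordinates.
Planted-fragment pairs embed a rigidly transformed copy of a chain segment
between decoy flanks, recording the true correspondence.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .geometry import GeometryError, Mapping, PointSequence

__all__ = ["generate_chain", "plant_common_fragment", "lattice_rotations"]

_SQRT3 = math.sqrt(3.0)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_chain(n: int, bond: float = 3.8, scale: int = 1,
                   seed: int | None = None, integral: bool = True,
                   globular: bool = False) -> PointSequence:
    """Random-walk chain of ``n`` points starting at the origin.

    Steps have fixed length ``bond`` in uniformly random directions;
    coordinates are multiplied by ``scale`` and, when ``integral``, rounded
    to integers (stretching a step by at most sqrt(3) lattice units).  In
    ``globular`` mode the walk is confined to a ball of radius
    ``O(n**(1/3))`` by rejection, modelling compact structures.
    """
    if n < 1:
        raise GeometryError("n must be >= 1")
    if bond <= 0 or scale < 1:
        raise GeometryError("bond must be positive and scale >= 1")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    radius = bond * max(2.0, 1.5 * n ** (1.0 / 3.0)) if globular else None
    for k in range(1, n):
        for _ in range(1000):
            step = _unit_vectors(rng, 1)[0] * bond
            nxt = coords[k - 1] + step
            if radius is None or np.linalg.norm(nxt) <= radius:
                break
        else:  # pragma: no cover - pull back toward the center as last resort
            direction = -coords[k - 1] / np.linalg.norm(coords[k - 1])
            nxt = coords[k - 1] + direction * bond
        coords[k] = nxt
    coords = coords * scale
    cap = bond * scale
    if integral:
        coords = np.round(coords)
        cap += _SQRT3
    return PointSequence(coords, name=f"chain-n{n}", integral=integral,
                         protein_mode=True, bond_cap=cap)


def lattice_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the integer lattice (signed permutations)."""
    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            R = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                R[row, col] = s
            if round(np.linalg.det(R)) == 1:
                out.append(R)
    return out


def plant_common_fragment(P: PointSequence, start: int, length: int,
                          noise: float = 0.0, decoys: int = 4,
                          seed: int | None = None,
                          bond: float = 3.8, scale: int = 1,
                          ) -> tuple[PointSequence, Mapping]:
    """Embed a transformed copy of ``P[start:start+length]`` in a decoy chain.

    With ``noise == 0`` the rigid motion is an exact lattice symmetry
    (a signed-permutation rotation plus an integer translation), so the
    planted fragment stays exactly congruent after rounding and
    ``LCP(theta=0)`` recovers at least ``length`` pairs.  With positive
    ``noise`` a generic random rotation is used and isotropic Gaussian
    noise of that scale is added per point before re-rounding.

    Returns the decorated Q chain and the ground-truth mapping
    ``(start + i, n_prefix_decoys + i)``.
    """
    n = len(P)
    if not (0 <= start and start + length <= n and length >= 1):
        raise GeometryError("fragment must lie inside P")
    if noise < 0 or decoys < 0:
        raise GeometryError("noise and decoys must be non-negative")
    rng = np.random.default_rng(seed)
    frag = P.coords[start:start + length].copy()
    span = max(int(np.abs(P.coords).max()), 1)
    if noise == 0 and P.integral:
        rots = lattice_rotations()
        R = rots[rng.integers(len(rots))]
        t = rng.integers(-span, span + 1, size=3).astype(float)
        moved = frag @ R.T + t
    else:
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-span, span, size=3)
        moved = frag @ R.T + t + rng.normal(scale=noise, size=frag.shape)
    pre = decoys // 2
    post = decoys - pre
    step_cap = bond * scale
    pre_pts = []
    cur = moved[0]
    for _ in range(pre):
        cur = cur + _unit_vectors(rng, 1)[0] * step_cap
        pre_pts.append(cur.copy())
    pre_pts.reverse()
    post_pts = []
    cur = moved[-1]
    for _ in range(post):
        cur = cur + _unit_vectors(rng, 1)[0] * step_cap
        post_pts.append(cur.copy())
    blocks = [np.array(pre_pts).reshape(-1, 3), moved,
              np.array(post_pts).reshape(-1, 3)]
    coords = np.concatenate([b for b in blocks if len(b)])
    if P.integral:
        coords = np.round(coords)
    Q = PointSequence(coords, name=f"{P.name}-planted", integral=P.integral,
                      protein_mode=False)
    truth = Mapping(tuple((start + i, pre + i) for i in range(length)),
                    sequential=True)
    return Q, truth
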