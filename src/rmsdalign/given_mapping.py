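"""Model superposition: LCP/MAD over subsets of a known residue bijection.

With the correspondence fixed, each matched pair contributes a displacement
``w_i = q'_i - p'_i``.  Under a pure translation ``s`` (acting in ``w - s``
form) the residual of pair i is ``||w_i - s||``, so the locus where pairs i
and j tie is a plane in translation space.  The planes cut translation
space into cells on which the residual ordering is constant; scanning one
witness per cell and keeping the best prefix of its ordering solves MAD and
LCP exactly under translations.  Full rigid motions are handled by a
clearly-labelled rotation-grid heuristic on top of the exact translation
solve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    AlignmentResult,
    GeometryError,
    Mapping,
    PointSequence,
    RigidTransform,
    superpose,
)

__all__ = [
    "DisplacementSet",
    "SeparatingPlane",
    "Cell",
    "build_planes",
    "enumerate_cells",
    "mad_given_mapping_translation",
    "lcp_given_mapping_translation",
    "mad_given_mapping_rigid_sampled",
]

_REL_EPS = 1e-12


@dataclass(frozen=True)
class DisplacementSet:
    """Per-pair displacements ``w_i = q'_i - p'_i`` in the order of F."""

    w: np.ndarray  # (l, 3)

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(np.asarray(self.w, dtype=float))
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise GeometryError("w must have shape (l, 3)")
        arr.setflags(write=False)
        object.__setattr__(self, "w", arr)

    @classmethod
    def from_mapping(cls, P: PointSequence, Q: PointSequence,
                     F: Mapping) -> "DisplacementSet":
        F.validate_against(P, Q)
        return cls(Q.subset(F.j_indices) - P.subset(F.i_indices))

    def __len__(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class SeparatingPlane:
    """Locus of translations where pairs i and j have equal residuals.

    Points ``t`` on the plane satisfy ``normal . t = offset`` with
    ``normal = 2 (w_i - w_j)`` and ``offset = ||w_i||^2 - ||w_j||^2``.
    ``tied`` marks degenerate pairs with ``w_i == w_j`` (equal residuals
    everywhere; no plane exists).
    """

    i: int
    j: int
    normal: np.ndarray
    offset: float
    tied: bool = False


@dataclass(frozen=True)
class Cell:
    """One full-dimensional cell of the arrangement, with a witness point."""

    witness: np.ndarray
    signs: tuple[int, ...]
    order: tuple[int, ...] | None = None


def build_planes(D: DisplacementSet) -> list[SeparatingPlane]:
    """One separating plane per unordered pair of pairs with ``w_i != w_j``."""
    l = len(D)
    if l < 2:
        raise GeometryError("need at least two pairs")
    out = []
    for i, j in itertools.combinations(range(l), 2):
        wi, wj = D.w[i], D.w[j]
        if np.array_equal(wi, wj):
            out.append(SeparatingPlane(i, j, np.zeros(3), 0.0, tied=True))
            continue
        normal = 2.0 * (wi - wj)
        offset = float(wi @ wi - wj @ wj)
        out.append(SeparatingPlane(i, j, normal, offset))
    return out


def _unique_planes(planes: list[SeparatingPlane]) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate coincident planes; returns unit normals and offsets."""
    live = [pl for pl in planes if not pl.tied]
    if not live:
        return np.zeros((0, 3)), np.zeros(0)
    N = np.array([pl.normal for pl in live], dtype=float)
    o = np.array([pl.offset for pl in live], dtype=float)
    norms = np.linalg.norm(N, axis=1)
    N = N / norms[:, None]
    o = o / norms
    # canonical orientation (first nonzero component positive) for dedup
    lead = np.zeros(len(N))
    for col in range(3):
        mask = (lead == 0) & (np.abs(N[:, col]) > 1e-12)
        lead[mask] = N[mask, col]
    sign = np.where(lead < 0, -1.0, 1.0)
    N = N * sign[:, None]
    o = o * sign
    dec = np.round(np.column_stack([N, o]), 9)
    _, idx = np.unique(dec, axis=0, return_index=True)
    idx = np.sort(idx)
    return N[idx], o[idx]


def _witness_candidates(normals: np.ndarray, offsets: np.ndarray,
                        seeds: np.ndarray | None) -> np.ndarray:
    """Candidate points aimed at hitting every full-dimensional cell.

    Vertices of plane triples perturbed into the 8 normal octants, points on
    pairwise intersection lines, per-plane foot points, far-field points in
    normal/cross-product directions, deterministic random fill, and any
    caller-provided seed points.  Fully vectorized.
    """
    k = normals.shape[0]
    L = max(1.0, float(np.abs(offsets).max(initial=0.0)))
    pts: list[np.ndarray] = [np.zeros((1, 3))]
    if seeds is not None and len(seeds):
        pts.append(np.asarray(seeds, dtype=float))
    eps_scales = np.array([1e-6, 1e-3]) * L
    sign3 = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))  # (8, 3)
    sign2 = np.array(list(itertools.product((-1.0, 1.0), repeat=2)))  # (4, 2)

    tri_dirs = np.zeros((0, 3))
    if k >= 3:
        trip = np.array(list(itertools.combinations(range(k), 3)))
        A = normals[trip]                      # (T, 3, 3)
        dets = np.abs(np.linalg.det(A))
        good = dets > 1e-9
        if good.any():
            A = A[good]
            b = offsets[trip[good]]
            verts = np.linalg.solve(A, b[..., None])[..., 0]  # (T, 3)
            # direction d with A d = s puts the point exactly on sign
            # pattern s of the three defining planes
            rhs = np.broadcast_to(sign3.T, (A.shape[0], 3, 8))
            dirs = np.linalg.solve(A, rhs).transpose(0, 2, 1)  # (T, 8, 3)
            for eps in eps_scales:
                pts.append((verts[:, None, :] + eps * dirs).reshape(-1, 3))
            tri_dirs = dirs.reshape(-1, 3)
    pair_dirs = np.zeros((0, 3))
    line_dirs = np.zeros((0, 3))
    if k >= 2:
        pair = np.array(list(itertools.combinations(range(k), 2)))
        n1, n2 = normals[pair[:, 0]], normals[pair[:, 1]]
        cr = np.cross(n1, n2)
        nd = np.linalg.norm(cr, axis=1)
        good = nd > 1e-9
        if good.any():
            n1g, n2g, crg = n1[good], n2[good], cr[good] / nd[good, None]
            # point on the intersection line: solve [n1; n2; dir] x = [o1; o2; 0]
            A = np.stack([n1g, n2g, crg], axis=1)
            b = np.column_stack([offsets[pair[good, 0]],
                                 offsets[pair[good, 1]],
                                 np.zeros(int(good.sum()))])
            base = np.linalg.solve(A, b[..., None])[..., 0]
            # minimum-norm d with n1.d = s1, n2.d = s2 (exact sign pattern)
            two = np.stack([n1g, n2g], axis=1)       # (G, 2, 3)
            G = two @ two.transpose(0, 2, 1)         # (G, 2, 2)
            rhs = np.broadcast_to(sign2.T, (two.shape[0], 2, 4))
            d2 = two.transpose(0, 2, 1) @ np.linalg.solve(G, rhs)  # (G, 3, 4)
            d2 = d2.transpose(0, 2, 1)               # (G, 4, 3)
            for shift in (0.0, 2.0 * L, -2.0 * L):
                p0 = base + shift * crg
                for eps in eps_scales:
                    pts.append((p0[:, None, :] + eps * d2).reshape(-1, 3))
            pair_dirs = d2.reshape(-1, 3)
            line_dirs = np.concatenate([crg, -crg])
    rng = np.random.default_rng(0)
    rand_dirs = rng.normal(size=(512, 3))
    rand_dirs /= np.linalg.norm(rand_dirs, axis=1, keepdims=True)
    far_all = np.concatenate(
        [normals, -normals, pair_dirs, line_dirs, tri_dirs, rand_dirs])
    nrm = np.linalg.norm(far_all, axis=1)
    far_all = far_all[nrm > 1e-9] / nrm[nrm > 1e-9, None]
    R_far = 5.0 * L + 1.0
    pts.append(far_all * R_far)
    foot = offsets[:, None] * normals
    for eps in eps_scales:
        pts.append(foot + eps * normals)
        pts.append(foot - eps * normals)
    pts.append(rng.uniform(-2.0 * L, 2.0 * L, size=(128, 3)))
    return np.concatenate(pts)


def _cell_witnesses(planes: list[SeparatingPlane],
                    seeds: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Witness points and sign vectors, one row per distinct cell."""
    normals, offsets = _unique_planes(planes)
    if normals.shape[0] == 0:
        return np.zeros((1, 3)), np.zeros((1, 0), dtype=np.int8)
    cand = _witness_candidates(normals, offsets, seeds)
    vals = cand @ normals.T - offsets
    L = max(1.0, float(np.abs(offsets).max(initial=0.0)))
    strict = np.all(np.abs(vals) > 1e-10 * L, axis=1)
    cand, vals = cand[strict], vals[strict]
    signs = np.where(vals > 0, 1, -1).astype(np.int8)
    k = signs.shape[1]
    if k <= 64:  # pack sign rows into integers for fast 1-D dedup
        bits = (signs > 0).astype(np.uint64)
        keys = bits @ (np.uint64(1) << np.arange(k, dtype=np.uint64))
        _, idx = np.unique(keys, return_index=True)
    else:
        _, idx = np.unique(signs, axis=0, return_index=True)
    idx = np.sort(idx)
    return cand[idx], signs[idx]


def _default_seeds(D: DisplacementSet | None) -> np.ndarray | None:
    if D is None:
        return None
    w = D.w
    seed_pts = [w, w.mean(axis=0, keepdims=True)]
    if len(w) >= 2:
        ii, jj = np.triu_indices(len(w), k=1)
        seed_pts.append((w[ii] + w[jj]) / 2.0)
    return np.concatenate(seed_pts)


def enumerate_cells(planes: list[SeparatingPlane],
                    displacements: DisplacementSet | None = None,
                    seeds: np.ndarray | None = None) -> list[Cell]:
    """Return at least one witness per full-dimensional arrangement cell.

    Cells are identified by their sign vector over the deduplicated planes.
    For k planes in general position the number of cells is
    ``1 + k + C(k,2) + C(k,3)``.  If ``displacements`` is given each cell
    also carries its residual ordering (ties broken by pair index).
    """
    if seeds is None:
        seeds = _default_seeds(displacements)
    witnesses, signs = _cell_witnesses(planes, seeds)
    orders = None
    if displacements is not None:
        orders = _residual_orders(displacements, witnesses)
    cells = []
    for idx in range(len(witnesses)):
        cells.append(Cell(
            witness=witnesses[idx],
            signs=tuple(int(s) for s in signs[idx]),
            order=tuple(int(i) for i in orders[idx]) if orders is not None else None,
        ))
    return cells


def _residual_orders(D: DisplacementSet, s: np.ndarray) -> np.ndarray:
    """Residual sort order of the pairs at each witness; (n_cells, l)."""
    diff = s[:, None, :] - D.w[None, :, :]
    resid = np.einsum("cld,cld->cl", diff, diff)
    return np.argsort(resid, axis=1, kind="stable")


def _prefix_costs(w_ordered: np.ndarray) -> np.ndarray:
    """cost[c, k-1] = optimal-translation squared sum of the first k pairs."""
    cs = np.cumsum(w_ordered, axis=-2)
    css = np.cumsum((w_ordered * w_ordered).sum(axis=-1), axis=-1)
    ks = np.arange(1, w_ordered.shape[-2] + 1)
    return np.maximum(css - (cs * cs).sum(axis=-1) / ks, 0.0)


def _translation_result(F: Mapping, chosen: list[int], D: DisplacementSet,
                        mode: str) -> AlignmentResult:
    chosen = sorted(chosen)
    sub = D.w[chosen]
    t_opt = sub.mean(axis=0)
    cost = float(((sub - t_opt) ** 2).sum())
    rmsd = math.sqrt(max(cost, 0.0) / len(chosen))
    pairs = tuple(F.pairs[c] for c in chosen)
    return AlignmentResult(
        mapping=Mapping(pairs, sequential=F.sequential),
        transform=RigidTransform(np.eye(3), -t_opt),
        rmsd=rmsd, size=len(chosen),
        metadata={"transform_class": "translation", "mode": mode,
                  "exact": True},
    )


def _arrangement_orders(D: DisplacementSet) -> np.ndarray:
    """Distinct residual orderings over all arrangement cells; (C, l)."""
    l = len(D)
    if l == 1:
        return np.zeros((1, 1), dtype=int)
    witnesses, _ = _cell_witnesses(build_planes(D), _default_seeds(D))
    orders = _residual_orders(D, witnesses)
    return np.unique(orders, axis=0)


def mad_given_mapping_translation(P: PointSequence, Q: PointSequence,
                                  F: Mapping, ell: int) -> AlignmentResult:
    """Exact translation-only MAD over subsets of the given bijection.

    For each arrangement cell, the first ``ell`` pairs of its residual
    ordering are scored at the subset's own optimal translation (its mean
    displacement); the global minimum equals the brute-force optimum over
    all ``ell``-subsets.
    """
    l = len(F)
    if not 1 <= ell <= l:
        raise GeometryError(f"ell must be in [1, {l}], got {ell}")
    D = DisplacementSet.from_mapping(P, Q, F)
    if ell == l:
        return _translation_result(F, list(range(l)), D, "mad")
    orders = _arrangement_orders(D)
    subsets = np.sort(orders[:, :ell], axis=1)
    subsets = np.unique(subsets, axis=0)
    sub_w = D.w[subsets]                         # (C, ell, 3)
    mu = sub_w.mean(axis=1, keepdims=True)
    costs = ((sub_w - mu) ** 2).sum(axis=(1, 2))
    best_cost = costs.min()
    near = np.flatnonzero(costs <= best_cost + 1e-12 * max(1.0, best_cost))
    chosen = min(tuple(subsets[i]) for i in near)  # deterministic tie-break
    return _translation_result(F, list(chosen), D, "mad")


def lcp_given_mapping_translation(P: PointSequence, Q: PointSequence,
                                  F: Mapping, theta: float) -> AlignmentResult:
    """Exact translation-only LCP: longest prefix of any cell order with
    optimal-translation RMSD within theta."""
    if theta < 0:
        raise GeometryError("theta must be non-negative")
    l = len(F)
    D = DisplacementSet.from_mapping(P, Q, F)
    if l == 1:
        return _translation_result(F, [0], D, "lcp")
    orders = _arrangement_orders(D)
    w_ord = D.w[orders]                          # (C, l, 3)
    costs = _prefix_costs(w_ord)                 # (C, l)
    ks = np.arange(1, l + 1)
    bound = ks * theta * theta
    ok = costs <= bound + _REL_EPS * np.maximum(1.0, bound)
    if not ok.any():
        return AlignmentResult(
            mapping=Mapping((), sequential=F.sequential),
            transform=RigidTransform.identity(), rmsd=0.0, size=0,
            metadata={"transform_class": "translation", "mode": "lcp",
                      "exact": True},
        )
    best_k = int((ok * ks).max(axis=1).max())
    cand_cells = np.flatnonzero(ok[:, best_k - 1])
    best = None
    for c in cand_cells:
        chosen = tuple(sorted(int(i) for i in orders[c, :best_k]))
        key = (float(costs[c, best_k - 1]), chosen)
        if best is None or key < best:
            best = key
    return _translation_result(F, list(best[1]), D, "lcp")


def _euler_grid(resolution: int) -> np.ndarray:
    """Uniform Euler-angle rotation grid; resolution 1 yields the identity."""
    from scipy.spatial.transform import Rotation

    if resolution < 1:
        raise GeometryError("grid resolution must be >= 1")
    if resolution == 1:
        return np.eye(3)[None, :, :]
    alpha = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    beta = np.linspace(0.0, np.pi, max(resolution // 2 + 1, 2))
    gamma = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    angles = np.array(list(itertools.product(alpha, beta, gamma)))
    return Rotation.from_euler("zyz", angles).as_matrix()


def mad_given_mapping_rigid_sampled(P: PointSequence, Q: PointSequence,
                                    F: Mapping, ell: int,
                                    rotation_grid: int = 12) -> AlignmentResult:
    """Heuristic rigid MAD over the given bijection (NOT exact).

    Samples rotations on a uniform Euler-angle grid, runs the exact
    translation solve for each, and keeps the best; the chosen subset is
    finally re-superposed.  The result RMSD is an upper bound on the exact
    rigid optimum; the exact sign-condition machinery over full rigid
    motions is out of scope.
    """
    l = len(F)
    if not 1 <= ell <= l:
        raise GeometryError(f"ell must be in [1, {l}], got {ell}")
    F.validate_against(P, Q)
    p = P.subset(F.i_indices)
    q = Q.subset(F.j_indices)
    best: tuple[float, tuple[int, ...]] | None = None
    for R in _euler_grid(rotation_grid):
        D = DisplacementSet(q @ R.T - p)
        if ell == l:
            chosen = tuple(range(l))
            sub = D.w
            mu = sub.mean(axis=0)
            cost = float(((sub - mu) ** 2).sum())
            if best is None or (cost, chosen) < best:
                best = (cost, chosen)
            continue
        orders = _arrangement_orders(D)
        subsets = np.unique(np.sort(orders[:, :ell], axis=1), axis=0)
        sub_w = D.w[subsets]
        mu = sub_w.mean(axis=1, keepdims=True)
        costs = ((sub_w - mu) ** 2).sum(axis=(1, 2))
        c = int(costs.argmin())
        key = (float(costs[c]), tuple(int(i) for i in subsets[c]))
        if best is None or key < best:
            best = key
    chosen = sorted(best[1])
    mapping = Mapping(tuple(F.pairs[c] for c in chosen),
                      sequential=F.sequential)
    T_opt, rmsd_opt = superpose(P, Q, mapping)
    rmsd_grid = math.sqrt(best[0] / ell)
    return AlignmentResult(
        mapping=mapping, transform=T_opt, rmsd=min(rmsd_opt, rmsd_grid),
        size=ell,
        metadata={"transform_class": "rigid", "mode": "mad",
                  "exact": False, "label": "heuristic (not exact)",
                  "rotation_grid": rotation_grid,
                  "grid_rmsd": rmsd_grid},
    )
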