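"""Brute-force reference solvers.  Exact by construction, exponential in l.

Every optimization in the package is cross-checked against these at tiny
problem sizes.  Comparisons between candidate subsets use squared residual
sums scaled by the subset size, so integer instances compare exactly.
"""

from __future__ import annotations

import itertools
import math

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
    "brute_force_mad",
    "brute_force_lcp",
    "brute_force_mad_fixed",
    "brute_force_lcp_fixed",
    "brute_force_mad_translation",
]

DEFAULT_BUDGET = 10 ** 6


class BudgetExceeded(GeometryError):
    """The brute-force search space exceeds the configured budget."""


def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def _check_budget(n: int, m: int, ell: int, sequential: bool,
                  budget: int) -> None:
    count = _comb(n, ell) * _comb(m, ell)
    if not sequential:
        count *= math.factorial(ell)
    if count > budget:
        raise BudgetExceeded(
            f"{count} candidate alignments exceed budget {budget}")


def brute_force_mad(P: PointSequence, Q: PointSequence, ell: int,
                    sequential: bool = True,
                    budget: int = DEFAULT_BUDGET) -> AlignmentResult:
    """Exhaustive MAD: superpose every ell-subset pair (and bijection)."""
    n, m = len(P), len(Q)
    if not 1 <= ell <= min(n, m):
        raise GeometryError(f"ell must be in [1, {min(n, m)}], got {ell}")
    _check_budget(n, m, ell, sequential, budget)
    best: tuple[float, tuple, RigidTransform] | None = None
    for isub in itertools.combinations(range(n), ell):
        for jsub in itertools.combinations(range(m), ell):
            j_orders = [jsub] if sequential else itertools.permutations(jsub)
            for jord in j_orders:
                pairs = tuple(zip(isub, jord))
                mapping = Mapping(pairs, sequential=sequential)
                T, rmsd = superpose(P, Q, mapping)
                # compare squared sums scaled by size: exact on integers
                key = (ell * rmsd * rmsd, pairs)
                if best is None or key < (best[0], best[1]):
                    best = (key[0], pairs, T)
    cost, pairs, T = best
    return AlignmentResult(
        mapping=Mapping(pairs, sequential=sequential), transform=T,
        rmsd=math.sqrt(cost / ell), size=ell,
        metadata={"oracle": True, "mode": "mad"},
    )


def brute_force_lcp(P: PointSequence, Q: PointSequence, theta: float,
                    sequential: bool = True,
                    budget: int = DEFAULT_BUDGET) -> AlignmentResult:
    """Exhaustive LCP: largest ell whose brute-force MAD is within theta."""
    if theta < 0:
        raise GeometryError("theta must be non-negative")
    for ell in range(min(len(P), len(Q)), 0, -1):
        res = brute_force_mad(P, Q, ell, sequential=sequential, budget=budget)
        if res.rmsd <= theta + 1e-9:
            return AlignmentResult(
                mapping=res.mapping, transform=res.transform, rmsd=res.rmsd,
                size=res.size, metadata={"oracle": True, "mode": "lcp"})
    return AlignmentResult(
        mapping=Mapping((), sequential=sequential),
        transform=RigidTransform.identity(), rmsd=0.0, size=0,
        metadata={"oracle": True, "mode": "lcp"})


def _fixed_cost_matrix(P: PointSequence, Q: PointSequence,
                       T: RigidTransform) -> np.ndarray:
    tq = T.apply(Q.coords)
    diff = P.coords[:, None, :] - tq[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def brute_force_mad_fixed(P: PointSequence, Q: PointSequence,
                          T: RigidTransform, ell: int,
                          sequential: bool = True,
                          budget: int = DEFAULT_BUDGET) -> float:
    """Minimum fixed-transform squared sum over every ell-pair alignment."""
    n, m = len(P), len(Q)
    if not 1 <= ell <= min(n, m):
        raise GeometryError(f"ell must be in [1, {min(n, m)}], got {ell}")
    _check_budget(n, m, ell, sequential, budget)
    d = _fixed_cost_matrix(P, Q, T)
    isubs = np.array(list(itertools.combinations(range(n), ell)))
    if sequential:
        jsubs = np.array(list(itertools.combinations(range(m), ell)))
    else:
        jsubs = np.array([perm
                          for comb in itertools.combinations(range(m), ell)
                          for perm in itertools.permutations(comb)])
    costs = d[isubs[:, None, :], jsubs[None, :, :]].sum(axis=2)
    return float(costs.min())


def brute_force_lcp_fixed(P: PointSequence, Q: PointSequence,
                          T: RigidTransform, theta: float,
                          sequential: bool = True,
                          budget: int = DEFAULT_BUDGET) -> int:
    """Largest k whose minimum fixed-transform squared sum is <= k theta^2."""
    best = 0
    for k in range(1, min(len(P), len(Q)) + 1):
        cost = brute_force_mad_fixed(P, Q, T, k, sequential=sequential,
                                     budget=budget)
        bound = k * theta * theta
        if cost <= bound + 1e-12 * max(1.0, bound):
            best = k
    return best


def brute_force_mad_translation(w: np.ndarray, ell: int) -> tuple[float, tuple[int, ...]]:
    """Translation-only MAD over displacement subsets (closed form per subset).

    Returns ``(rmsd, chosen_indices)`` minimizing the about-mean scatter of
    the chosen displacements.
    """
    l = w.shape[0]
    if not 1 <= ell <= l:
        raise GeometryError("ell out of range")
    best: tuple[float, tuple[int, ...]] | None = None
    for sub in itertools.combinations(range(l), ell):
        ws = w[list(sub)]
        mu = ws.mean(axis=0)
        cost = float(((ws - mu) ** 2).sum())
        if best is None or (cost, sub) < best:
            best = (cost, sub)
    return math.sqrt(best[0] / ell), best[1]
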