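"""Solving MAD by binary search over the threshold of an LCP solver.

Works in the integral-coordinate regime only: there the achievable RMSD
values of fixed-size alignments are separated by a computable gap, so the
bisection over the threshold terminates with the exact optimum.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .bounds import resolution_gap, rmsd_upper_bound
from .geometry import (
    AlignmentResult,
    GeometryError,
    Mapping,
    PointSequence,
    superpose,
)

__all__ = ["mad_via_lcp", "iteration_budget"]

LCPSolver = Callable[[PointSequence, PointSequence, float], AlignmentResult]


class SolverNotMonotone(GeometryError):
    """The LCP solver reported sizes inconsistent with threshold monotonicity."""


def iteration_budget(c_max: float, ell: int) -> int:
    """Bisections needed to shrink ``[0, ell*c_max]`` below the RMSD gap."""
    gap = resolution_gap(c_max, ell)
    return max(1, math.ceil(math.log2((ell * c_max) / gap)))


def _trim_to_ell(P: PointSequence, Q: PointSequence, res: AlignmentResult,
                 ell: int) -> AlignmentResult:
    """Re-report a feasible solution at exactly ell pairs.

    Drops the largest-residual pairs under the solution's own optimal
    transform (which cannot increase the RMSD) and re-superposes.
    """
    if res.size == ell:
        T, rmsd = superpose(P, Q, res.mapping)
        return AlignmentResult(mapping=res.mapping, transform=T, rmsd=rmsd,
                               size=ell, metadata=dict(res.metadata))
    T, _ = superpose(P, Q, res.mapping)
    p = P.subset(res.mapping.i_indices)
    q = Q.subset(res.mapping.j_indices)
    resid = np.linalg.norm(T.apply(q) - p, axis=1)
    keep = np.sort(np.argsort(resid, kind="stable")[:ell])
    pairs = tuple(res.mapping.pairs[k] for k in keep)
    mapping = Mapping(pairs, sequential=res.mapping.sequential)
    T2, rmsd2 = superpose(P, Q, mapping)
    return AlignmentResult(mapping=mapping, transform=T2, rmsd=rmsd2,
                           size=ell, metadata=dict(res.metadata))


def mad_via_lcp(lcp_solver: LCPSolver, P: PointSequence, Q: PointSequence,
                ell: int, upper_start: str = "table",
                log: Callable[[str], None] | None = None) -> AlignmentResult:
    """Binary-search a MAD optimum out of an exact LCP solver.

    Maintains an interval ``[lo, hi]`` starting at ``[0, ell * c_max]``,
    shrinking ``hi`` whenever the LCP solution at the midpoint has size at
    least ``ell`` and raising ``lo`` otherwise, until the interval is below
    the integer-coordinate resolution gap.  The last feasible solution,
    re-reported at exactly ``ell`` pairs, attains the exact MAD optimum.

    ``upper_start`` is ``"table"`` (``ell * c_max``) or ``"lemma"``
    (``4 sqrt(3) c_max``, always feasible and tighter for ``ell >= 7``).
    """
    if not (P.integral and Q.integral):
        raise GeometryError(
            "integral coordinates required: the bisection terminates only "
            "in the integer regime")
    if not 1 <= ell <= min(len(P), len(Q)):
        raise GeometryError(f"ell must be in [1, {min(len(P), len(Q))}]")
    c_max = max(P.c_max, Q.c_max, 1.0)
    gap = resolution_gap(c_max, ell)
    if upper_start == "table":
        hi = ell * c_max
    elif upper_start == "lemma":
        hi = rmsd_upper_bound(c_max)
    else:
        raise GeometryError(f"unknown upper_start {upper_start!r}")
    lo = 0.0
    max_feas_fail = -math.inf  # largest theta seen infeasible
    min_feas_ok = math.inf     # smallest theta seen feasible

    def probe(theta: float) -> AlignmentResult:
        nonlocal max_feas_fail, min_feas_ok
        res = lcp_solver(P, Q, theta)
        feasible = res.size >= ell
        if feasible:
            min_feas_ok = min(min_feas_ok, theta)
        else:
            max_feas_fail = max(max_feas_fail, theta)
        if max_feas_fail >= min_feas_ok:
            raise SolverNotMonotone("solver not monotone")
        if log is not None:
            log(f"theta={theta:.9g} feasible={feasible} size={res.size}")
        return res

    best = probe(hi)
    if best.size < ell:
        # the printed interval start ell*c_max is not provably feasible for
        # small ell; fall back to the always-feasible coordinate-box bound
        hi = rmsd_upper_bound(c_max)
        best = probe(hi)
        if best.size < ell:
            raise SolverNotMonotone(
                "solver infeasible at the guaranteed upper bound")
    budget = iteration_budget(c_max, ell)
    if hi - lo > ell * c_max:  # fallback widened the interval
        budget = max(budget, math.ceil(math.log2((hi - lo) / gap)))
    iterations = 0
    while hi - lo > gap and iterations < budget:
        mid = 0.5 * (lo + hi)
        res = probe(mid)
        if res.size >= ell:
            hi = mid
            best = res
        else:
            lo = mid
        iterations += 1
    out = _trim_to_ell(P, Q, best, ell)
    out.metadata.update({"iterations": iterations, "budget": budget,
                         "gap": gap, "interval": (lo, hi)})
    return out
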