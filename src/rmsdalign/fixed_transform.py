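"""LCP and MAD when the superposition is already known.

Sequential alignments are found with a three-index prefix DP over
``M[i, j; k]`` — the minimum squared-residual sum of ``k`` matched pairs
within the prefixes ``p_1..p_i`` and ``q_1..q_j`` — and non-sequential ones
with successive-shortest-path min-cost matching on the bipartite pair graph.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    AlignmentResult,
    GeometryError,
    Mapping,
    PointSequence,
    RigidTransform,
)

__all__ = [
    "DPTable",
    "build_dp",
    "lcp_fixed_transform",
    "mad_fixed_transform",
    "nonsequential_fixed_transform",
]

INF = np.inf

# relative slack for threshold tests; on integral instances squared sums are
# exact integers in float64 and a 1e-12 relative slack can never flip a
# strict integer inequality (the gap is >= 1)
_REL_EPS = 1e-12


def _cost_matrix(P: PointSequence, Q: PointSequence, T: RigidTransform) -> np.ndarray:
    """d[i, j] = squared residual of matching p_i with T(q_j)."""
    tq = T.apply(Q.coords)
    diff = P.coords[:, None, :] - tq[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


@dataclass(frozen=True)
class DPTable:
    """The filled prefix table; ``cost`` has shape (n+1, m+1, k_max+1)."""

    cost: np.ndarray
    d: np.ndarray  # pairwise squared residuals, shape (n, m)
    k_max: int

    def best_for_size(self, k: int) -> float:
        return float(self.cost[-1, -1, k])


def build_dp(P: PointSequence, Q: PointSequence, T: RigidTransform,
             k_max: int) -> DPTable:
    """Fill the three-index table by the match/skip recurrence.

    ``M[i,j;k] = min(M[i-1,j-1;k-1] + d_ij, M[i,j-1;k], M[i-1,j;k])`` with
    ``M[i,j;0] = 0`` and ``M[i,j;k] = +inf`` for ``k > min(i, j)``.
    Runtime O(n m k_max).
    """
    n, m = len(P), len(Q)
    if not 1 <= k_max <= min(n, m):
        raise GeometryError(f"k_max must be in [1, {min(n, m)}], got {k_max}")
    d = _cost_matrix(P, Q, T)
    M = np.full((n + 1, m + 1, k_max + 1), INF)
    M[:, :, 0] = 0.0
    for k in range(1, k_max + 1):
        prev = M[:, :, k - 1]
        cur = M[:, :, k]
        for i in range(k, n + 1):
            # candidate = min(diagonal-match, skip-i); running min gives skip-j
            cand = np.minimum(prev[i - 1, :-1] + d[i - 1, :], cur[i - 1, 1:])
            cur[i, 1:] = np.minimum.accumulate(cand)
    return DPTable(cost=M, d=d, k_max=k_max)


def _traceback(table: DPTable, n: int, m: int, k: int) -> list[tuple[int, int]]:
    """Recover one optimal k-pair sequential mapping.

    Tie-break order: diagonal match, then j-skip, then i-skip.
    """
    M, d = table.cost, table.d
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while k > 0:
        v = M[i, j, k]
        if i >= 1 and j >= 1 and M[i - 1, j - 1, k - 1] + d[i - 1, j - 1] <= v + 1e-12 * max(1.0, abs(v)):
            pairs.append((i - 1, j - 1))
            i, j, k = i - 1, j - 1, k - 1
        elif j >= 1 and M[i, j - 1, k] <= v:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return pairs


def _result_from_pairs(pairs, T: RigidTransform, cost: float,
                       sequential: bool, **meta) -> AlignmentResult:
    k = len(pairs)
    rmsd = math.sqrt(max(cost, 0.0) / k) if k else 0.0
    return AlignmentResult(
        mapping=Mapping(tuple(pairs), sequential=sequential),
        transform=T, rmsd=rmsd, size=k,
        metadata={"fixed_transform": True, **meta},
    )


def lcp_fixed_transform(P: PointSequence, Q: PointSequence, T: RigidTransform,
                        theta: float) -> AlignmentResult:
    """Largest sequential alignment whose squared sum is within ``k * theta**2``."""
    if theta < 0:
        raise GeometryError("theta must be non-negative")
    k_max = min(len(P), len(Q))
    table = build_dp(P, Q, T, k_max)
    best_k = 0
    for k in range(1, k_max + 1):
        bound = k * theta * theta
        if table.best_for_size(k) <= bound + _REL_EPS * max(1.0, bound):
            best_k = k
    if best_k == 0:
        return _result_from_pairs([], T, 0.0, sequential=True, mode="lcp")
    pairs = _traceback(table, len(P), len(Q), best_k)
    return _result_from_pairs(pairs, T, table.best_for_size(best_k),
                              sequential=True, mode="lcp")


def mad_fixed_transform(P: PointSequence, Q: PointSequence, T: RigidTransform,
                        ell: int) -> AlignmentResult:
    """Minimum-cost sequential alignment of exactly ``ell`` pairs."""
    if not 1 <= ell <= min(len(P), len(Q)):
        raise GeometryError(f"ell must be in [1, {min(len(P), len(Q))}], got {ell}")
    table = build_dp(P, Q, T, ell)
    pairs = _traceback(table, len(P), len(Q), ell)
    return _result_from_pairs(pairs, T, table.best_for_size(ell),
                              sequential=True, mode="mad")


# ---------------------------------------------------------------------------
# non-sequential case: successive shortest paths on the bipartite graph
# ---------------------------------------------------------------------------

def _min_cost_matching_profile(d: np.ndarray) -> tuple[list[float], list[dict[int, int]]]:
    """Optimal matching cost for every cardinality k = 1..min(n, m).

    Successive shortest augmenting paths with Johnson potentials; after the
    k-th augmentation the current matching is a minimum-cost k-matching.
    Returns (costs, matchings) where matchings[k-1] maps i -> j.
    """
    n, m = d.shape
    pot_p = np.zeros(n)
    pot_q = np.zeros(m)
    match_p = np.full(n, -1)  # i -> j
    match_q = np.full(m, -1)  # j -> i
    costs: list[float] = []
    snapshots: list[dict[int, int]] = []
    total = 0.0
    for _ in range(min(n, m)):
        # Dijkstra from all free P nodes over reduced costs
        dist_p = np.full(n, INF)
        dist_q = np.full(m, INF)
        parent_q = np.full(m, -1)
        heap: list[tuple[float, int, int]] = []
        for i in range(n):
            if match_p[i] == -1:
                dist_p[i] = 0.0
                heap.append((0.0, 0, i))  # (dist, side 0=P/1=Q, node)
        heapq.heapify(heap)
        best_free_q = -1
        while heap:
            du, side, u = heapq.heappop(heap)
            if side == 0:
                if du > dist_p[u]:
                    continue
                for j in range(m):
                    if match_p[u] == j:
                        continue
                    w = du + d[u, j] + pot_p[u] - pot_q[j]
                    if w < dist_q[j] - 1e-15:
                        dist_q[j] = w
                        parent_q[j] = u
                        heapq.heappush(heap, (w, 1, j))
            else:
                if du > dist_q[u]:
                    continue
                i = match_q[u]
                if i != -1:
                    # residual backward arc q -> matched p, cost -d[i, u]
                    w = du - d[i, u] + pot_q[u] - pot_p[i]
                    if w < dist_p[i] - 1e-15:
                        dist_p[i] = w
                        heapq.heappush(heap, (w, 0, i))
        free_q = [j for j in range(m) if match_q[j] == -1 and dist_q[j] < INF]
        if not free_q:
            break
        # real path cost = reduced distance + potential of the sink
        best_free_q = min(free_q, key=lambda j: (dist_q[j] + pot_q[j], j))
        # update potentials
        finite_p = dist_p < INF
        finite_q = dist_q < INF
        pot_p[finite_p] += dist_p[finite_p]
        pot_q[finite_q] += dist_q[finite_q]
        # augment along parent chain
        j = best_free_q
        while j != -1:
            i = parent_q[j]
            nxt = match_p[i]
            match_p[i] = j
            match_q[j] = i
            j = nxt if nxt != -1 else -1
        total = float(sum(d[i, match_p[i]] for i in range(n) if match_p[i] != -1))
        costs.append(total)
        snapshots.append({i: int(match_p[i]) for i in range(n) if match_p[i] != -1})
    return costs, snapshots


def nonsequential_fixed_transform(P: PointSequence, Q: PointSequence,
                                  T: RigidTransform, mode: str,
                                  theta: float | None = None,
                                  ell: int | None = None) -> AlignmentResult:
    """Order-free LCP/MAD at a fixed transform via min-cost matching.

    ``mode`` is ``"lcp"`` (requires ``theta``) or ``"mad"`` (requires
    ``ell``).  The k-pair matching cost profile is exact for every k, so LCP
    picks the largest k with cost ≤ k·theta², MAD returns the ell-pair
    minimum.
    """
    d = _cost_matrix(P, Q, T)
    costs, snapshots = _min_cost_matching_profile(d)
    if mode == "mad":
        if ell is None or not 1 <= ell <= min(len(P), len(Q)):
            raise GeometryError("ell out of range")
        pairs = sorted(snapshots[ell - 1].items())
        return _result_from_pairs(pairs, T, costs[ell - 1], sequential=False,
                                  mode="mad")
    if mode == "lcp":
        if theta is None or theta < 0:
            raise GeometryError("theta must be non-negative")
        best_k = 0
        for k, cost in enumerate(costs, start=1):
            bound = k * theta * theta
            if cost <= bound + _REL_EPS * max(1.0, bound):
                best_k = k
        if best_k == 0:
            return _result_from_pairs([], T, 0.0, sequential=False, mode="lcp")
        pairs = sorted(snapshots[best_k - 1].items())
        return _result_from_pairs(pairs, T, costs[best_k - 1], sequential=False,
                                  mode="lcp")
    raise GeometryError(f"unknown mode {mode!r}")
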