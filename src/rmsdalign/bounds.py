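"""RMSD lower and upper bounds for point sets with bounded coordinates.

The lower bound compares intra-structure distances over a pairing induced
by a permutation; the resolution gap is the smallest nonzero RMSD (and the
minimum spacing between distinct achievable RMSD values) in the
integer-coordinate regime; the upper bound caps any superposition RMSD of
structures confined to ``[-c_max, c_max]^3``.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import GeometryError, Mapping, PointSequence

__all__ = ["pairdist_lower_bound", "resolution_gap", "rmsd_upper_bound"]


def pairdist_lower_bound(P: PointSequence, Q: PointSequence, mapping: Mapping,
                         pi: list[int] | np.ndarray) -> float:
    """Distance-difference lower bound on the superposition RMSD.

    With ``h = floor(l/2)``, pairs ``(pi[i], pi[i+h])`` for ``i < h`` are
    compared between the two structures:

        sqrt( (1 / (2 l)) * sum_i |dP_i - dQ_i|^2 )  <=  RMSD

    where dP_i, dQ_i are the intra-structure distances of the paired points.
    """
    l = len(mapping)
    if l < 2:
        raise GeometryError("need at least two mapped pairs")
    pi = np.asarray(pi, dtype=int)
    if sorted(pi.tolist()) != list(range(l)):
        raise GeometryError("pi is not a permutation of 0..l-1")
    p = P.subset(mapping.i_indices)
    q = Q.subset(mapping.j_indices)
    h = l // 2
    a, b = pi[:h], pi[h:2 * h]
    dp = np.linalg.norm(p[a] - p[b], axis=1)
    dq = np.linalg.norm(q[a] - q[b], axis=1)
    return math.sqrt(float(((dp - dq) ** 2).sum()) / (2.0 * l))


def resolution_gap(c_max: float, ell: int) -> float:
    """Minimum nonzero RMSD for integer coordinates in ``[-c_max, c_max]^3``.

    Two integer squared distances within the box differ by at least 1, and
    the largest possible squared distance is ``12 c_max^2``, so the smallest
    nonzero distance difference is ``sqrt(12 c_max^2) - sqrt(12 c_max^2 - 1)``;
    dividing by ``sqrt(2 ell)`` gives the RMSD gap.
    """
    if ell < 1:
        raise GeometryError("ell must be >= 1")
    if c_max == 0:
        raise GeometryError("c_max must be positive (no nonzero RMSD exists)")
    if c_max < 1:
        raise GeometryError("c_max must be >= 1 in the integral regime")
    top = 12.0 * c_max * c_max
    return (math.sqrt(top) - math.sqrt(top - 1.0)) / math.sqrt(2.0 * ell)


def rmsd_upper_bound(c_max: float) -> float:
    """``4 sqrt(3) c_max``: cap on any RMSD within ``[-c_max, c_max]^3``."""
    if c_max < 0:
        raise GeometryError("c_max must be non-negative")
    return math.sqrt(48.0) * c_max
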