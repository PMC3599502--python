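"""Readers and writers for coordinate tables, PDB C-alpha traces, mappings."""

from __future__ import annotations

import warnings
from pathlib import Path
import numpy as np

from .geometry import GeometryError, Mapping, PointSequence

__all__ = [
    "read_table",
    "write_table",
    "read_pdb_ca",
    "read_pairs",
    "scale_to_integral",
]


def read_table(path, name: str = "", integral: bool | None = None) -> PointSequence:
    """Read one point per line, ``x y z`` whitespace- or comma-separated."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise GeometryError(f"expected 3 coordinates per line, got: {raw!r}")
        rows.append([float(x) for x in parts])
    if not rows:
        raise GeometryError(f"no coordinates found in {path}")
    coords = np.array(rows, dtype=float)
    if integral is None:
        integral = bool(np.array_equal(coords, np.round(coords)))
    return PointSequence(coords, name=name or Path(path).stem, integral=integral)


def write_table(path, P: PointSequence, delimiter: str = " ") -> None:
    fmt = "%d" if P.integral else "%.6f"
    np.savetxt(path, P.coords, fmt=fmt, delimiter=delimiter)


def read_pdb_ca(path, chain: str | None = None) -> list[PointSequence]:
    """Extract C-alpha traces from a PDB file, one PointSequence per chain.

    Only atoms named ``CA`` are used; for disordered atoms the first altloc
    is kept.  Coordinates are in Angstrom with the file's 3-decimal
    precision preserved.
    """
    from Bio.PDB import PDBParser  # deferred: biopython import is slow

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models(), None)
    if model is None:
        raise GeometryError(f"no C-alpha atoms found in {path}")
    out = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        coords = []
        for res in ch:
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                atom = sorted(atom.disordered_get_list(),
                              key=lambda a: a.get_altloc())[0]
            coords.append(atom.get_coord())
        if coords:
            out.append(PointSequence(np.array(coords, dtype=float),
                                     name=f"{Path(path).stem}:{ch.id}",
                                     protein_mode=False))
    if not out:
        raise GeometryError(f"no C-alpha atoms found in {path}")
    return out


def read_pairs(path, sequential: bool = True, one_based: bool = True) -> Mapping:
    """Read a TSV/whitespace list of (i, j) index pairs."""
    pairs = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise GeometryError(f"expected 2 indices per line, got: {raw!r}")
        i, j = int(parts[0]), int(parts[1])
        if one_based:
            i, j = i - 1, j - 1
        pairs.append((i, j))
    return Mapping(tuple(pairs), sequential=sequential)


def scale_to_integral(P: PointSequence, k: int = 3) -> PointSequence:
    """Multiply coordinates by 10**k and round, producing an integral copy.

    The default k=3 mirrors the 3-decimal coordinate precision of PDB files.
    """
    if k < 0:
        raise GeometryError("k must be non-negative")
    coords = np.round(P.coords * 10 ** k)
    # rounding can stretch a step by at most sqrt(3) lattice units
    cap = P.bond_cap * 10 ** k + np.sqrt(3.0)
    return PointSequence(coords, name=P.name, integral=True,
                         protein_mode=P.protein_mode, bond_cap=cap)
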