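# rmsdalign

Exact, oracle-checked solvers for protein structure alignment under the
RMSD: the **LCP** problem (largest common point set within an RMSD
threshold θ) and its minimization twin **MAD** (minimum RMSD at a fixed
alignment size ℓ), for ordered 3D point sequences (Cα traces).

## What's inside

| Module | Contents |
| --- | --- |
| `rmsdalign.geometry` | `PointSequence`, `RigidTransform`, `Mapping`, `AlignmentResult`; Kabsch superposition (proper rotations only), fixed-transform RMSD |
| `rmsdalign.fixed_transform` | LCP/MAD when the superposition is known: three-index prefix DP (sequential) and successive-shortest-path min-cost matching (non-sequential) |
| `rmsdalign.given_mapping` | Model superposition: exact translation-only LCP/MAD via a translation-space plane arrangement; labelled rotation-grid heuristic for full rigid motions |
| `rmsdalign.bounds` | Pairwise-distance lower bound, the integer-coordinate RMSD resolution gap, and the `4√3·c_max` upper bound |
| `rmsdalign.reduction` | MAD by binary search over an LCP solver's threshold (integral coordinates; terminates at the resolution gap) |
| `rmsdalign.lattice` | Pseudo-polynomial exact algorithm: centroid-translation and correlation-matrix lattices, SVD rotations, coverage-reported enumeration, exact-rational lattice membership checks |
| `rmsdalign.oracles` | Brute-force reference solvers (ground truth for every equivalence test) |
| `rmsdalign.synthetic` | Protein-like random-walk chains (3.8 Å step cap, integer rounding) and planted-fragment instances with known ground truth |
| `rmsdalign.io` | Plain coordinate tables, PDB Cα extraction, integer scaling |

Conventions: transforms map the second structure (Q) onto the first (P);
indices are 0-based internally and 1-based in reports; reflections are
never returned.

## CLI

The console script is `align`:

```sh
# synthetic pair with a planted congruent fragment + ground truth JSON
align simulate --n 12 --seed 4 --plant 2:5 --out-prefix sim

# LCP at a fixed superposition (transform file: 12 numbers, row-major R then t)
align fixed sim_P.txt sim_Q.txt --mode lcp --theta 0.5
align fixed sim_P.txt sim_Q.txt --mode mad --ell 4 --nonsequential

# model superposition over a known residue bijection (1-based pairs TSV)
align mapped sim_P.txt sim_Q.txt --pairs pairs.tsv --mode mad --ell 3

# bounds and the LCP->MAD bisection budget
align bounds --cmax 10 --ell 4

# MAD via the LCP binary-search reduction (tiny integral instances)
align mad sim_P.txt sim_Q.txt --ell 3 --via-lcp

# lattice enumeration over a restricted window, with a coverage report
align exact sim_P.txt sim_Q.txt --ell 2 --tp-range 0:1 --tq-range 0:1 --m-range 0:1
```

## Notes on exactness

- The full transform-lattice enumeration is astronomically large even for
  toy instances (the matrix lattice alone is ~10²¹ points at ℓ=2,
  c_max=2). Runs therefore take explicit candidate ranges and always
  report the fraction of the lattice scanned; exactness of the full
  algorithm is established by the lattice-membership property (checked in
  exact rational arithmetic), conditional exactness at the optimal lattice
  point, and the fixed-transform DP correctness.
- The rigid-motion mode of the given-mapping solver is a sampling
  heuristic and says so in its result metadata; the translation-only mode
  is exact and is verified against subset brute force.
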