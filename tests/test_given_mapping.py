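import itertools

import numpy as np
import pytest

from rmsdalign import (
    DisplacementSet,
    GeometryError,
    Mapping,
    PointSequence,
    SeparatingPlane,
    build_planes,
    enumerate_cells,
    lcp_given_mapping_translation,
    mad_given_mapping_rigid_sampled,
    mad_given_mapping_translation,
    superpose,
)
from rmsdalign.oracles import brute_force_mad_translation

from conftest import random_rotation


def seq(coords):
    return PointSequence(np.asarray(coords, dtype=float))


def displacement_instance(rng, l, lo=-4, hi=4):
    base = rng.integers(lo, hi + 1, size=(l, 3)).astype(float)
    w = rng.integers(lo, hi + 1, size=(l, 3)).astype(float)
    return seq(base), seq(base + w), Mapping.identity(l), w


class TestBuildPlanes:
    def test_two_pair_bisector(self):
        D = DisplacementSet(np.array([[0.0, 0, 0], [2, 0, 0]]))
        planes = build_planes(D)
        assert len(planes) == 1
        pl = planes[0]
        assert np.allclose(pl.normal, [-4.0, 0, 0])
        assert pl.offset == pytest.approx(-4.0)
        # plane is x = 1
        assert pl.normal @ np.array([1.0, 5.0, -2.0]) == pytest.approx(pl.offset)

    def test_tied_pair_flagged(self):
        D = DisplacementSet(np.array([[1.0, 2, 3], [1, 2, 3]]))
        planes = build_planes(D)
        assert planes[0].tied

    def test_on_plane_residuals_equal(self, rng):
        _, _, _, w = displacement_instance(rng, 5)
        D = DisplacementSet(w)
        for pl in build_planes(D):
            if pl.tied:
                continue
            # a point on the plane: foot of the origin perpendicular
            t = pl.offset * pl.normal / (pl.normal @ pl.normal)
            ri = np.linalg.norm(w[pl.i] - t)
            rj = np.linalg.norm(w[pl.j] - t)
            assert ri == pytest.approx(rj, abs=1e-9)

    def test_count_at_most_choose2(self, rng):
        _, _, _, w = displacement_instance(rng, 6)
        assert len(build_planes(DisplacementSet(w))) <= 15

    def test_needs_two_pairs(self):
        with pytest.raises(GeometryError):
            build_planes(DisplacementSet(np.zeros((1, 3))))


class TestEnumerateCells:
    @staticmethod
    def rand_planes(k, rng):
        return [SeparatingPlane(0, i + 1, rng.normal(size=3),
                                float(rng.normal())) for i in range(k)]

    @pytest.mark.parametrize("k,expected", [(1, 2), (3, 8), (4, 15)])
    def test_general_position_counts(self, k, expected, rng):
        for _ in range(3):
            cells = enumerate_cells(self.rand_planes(k, rng))
            assert len(cells) == expected

    def test_no_planes_single_cell(self):
        D = DisplacementSet(np.tile([1.0, 2, 3], (3, 1)))
        cells = enumerate_cells(build_planes(D), D)
        assert len(cells) == 1
        assert cells[0].order == (0, 1, 2)

    def test_sign_vectors_unique(self, rng):
        cells = enumerate_cells(self.rand_planes(5, rng))
        signs = {c.signs for c in cells}
        assert len(signs) == len(cells)

    def test_same_cell_same_order(self, rng):
        # ordering invariance: points sharing a sign vector sort identically
        _, _, _, w = displacement_instance(rng, 6)
        D = DisplacementSet(w)
        planes = build_planes(D)
        cells = enumerate_cells(planes, D)
        live = [(pl.normal, pl.offset) for pl in planes if not pl.tied]
        for cell in cells[:20]:
            for _ in range(5):
                probe = cell.witness + rng.normal(scale=1e-9, size=3)
                signs = tuple(
                    1 if n @ probe - o > 0 else -1 for n, o in live)
                resid = np.linalg.norm(w - probe, axis=1)
                order = tuple(np.argsort(resid, kind="stable"))
                # only compare when the probe stayed inside the cell
                cell_signs = tuple(
                    1 if n @ cell.witness - o > 0 else -1 for n, o in live)
                if signs == cell_signs:
                    assert order == cell.order


class TestMadTranslation:
    def test_pure_translation_zero(self, rng):
        base = rng.normal(size=(5, 3))
        P, Q = seq(base), seq(base + np.array([3.0, -1, 2]))
        for ell in (1, 3, 5):
            res = mad_given_mapping_translation(P, Q, Mapping.identity(5), ell)
            assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_picks_identical_displacements(self):
        base = np.zeros((3, 3))
        w = np.array([[0.0, 0, 0], [0, 0, 0], [6, 0, 0]])
        res = mad_given_mapping_translation(seq(base), seq(base + w),
                                            Mapping.identity(3), 2)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert [p[0] for p in res.mapping.pairs] == [0, 1]

    def test_matches_subset_brute_force(self, rng):
        for _ in range(25):
            l = int(rng.integers(2, 9))
            P, Q, F, w = displacement_instance(rng, l)
            ell = int(rng.integers(1, l + 1))
            res = mad_given_mapping_translation(P, Q, F, ell)
            bf_rmsd, _ = brute_force_mad_translation(w, ell)
            assert res.rmsd == pytest.approx(bf_rmsd, abs=1e-9)

    def test_prefix_optimality(self, rng):
        # chosen pairs are the ell smallest residuals at their own optimum
        P, Q, F, w = displacement_instance(rng, 7)
        ell = 3
        res = mad_given_mapping_translation(P, Q, F, ell)
        chosen = sorted(p[0] for p in res.mapping.pairs)
        t_opt = -res.transform.translation
        resid = np.linalg.norm(w - t_opt, axis=1)
        cutoff = max(resid[chosen])
        others = [i for i in range(7) if i not in chosen]
        assert all(resid[i] >= cutoff - 1e-9 for i in others)

    def test_ell_out_of_range(self, rng):
        P, Q, F, _ = displacement_instance(rng, 4)
        with pytest.raises(GeometryError, match="ell"):
            mad_given_mapping_translation(P, Q, F, 5)


class TestLcpTranslation:
    def test_huge_theta_takes_all(self, rng):
        P, Q, F, w = displacement_instance(rng, 6)
        theta = float(np.abs(w).sum())
        assert lcp_given_mapping_translation(P, Q, F, theta).size == 6

    def test_theta_zero_distinct_displacements(self, rng):
        base = rng.normal(size=(5, 3))
        w = np.arange(15, dtype=float).reshape(5, 3)
        res = lcp_given_mapping_translation(seq(base), seq(base + w),
                                            Mapping.identity(5), 0.0)
        assert res.size == 1

    def test_matches_subset_brute_force(self, rng):
        for _ in range(25):
            l = int(rng.integers(2, 9))
            P, Q, F, w = displacement_instance(rng, l)
            theta = float(rng.uniform(0, 4))
            res = lcp_given_mapping_translation(P, Q, F, theta)
            best = 0
            for ell in range(1, l + 1):
                bf_rmsd, _ = brute_force_mad_translation(w, ell)
                if bf_rmsd <= theta + 1e-9:
                    best = ell
            assert res.size == best


class TestRigidSampled:
    def test_grid_one_equals_translation_only(self, rng):
        P, Q, F, _ = displacement_instance(rng, 5)
        tr = mad_given_mapping_translation(P, Q, F, 3)
        rg = mad_given_mapping_rigid_sampled(P, Q, F, 3, rotation_grid=1)
        # grid of 1 samples only the identity rotation; re-superposition of
        # the chosen subset may only improve the rmsd
        assert rg.metadata["grid_rmsd"] == pytest.approx(tr.rmsd, abs=1e-9)
        assert rg.rmsd <= tr.rmsd + 1e-9
        assert rg.metadata["label"] == "heuristic (not exact)"

    def test_congruent_recovered(self, rng):
        base = rng.normal(size=(5, 3)) * 3
        R0 = random_rotation(rng)
        Q = seq(base @ R0.T + np.array([1.0, 2, 3]))
        res = mad_given_mapping_rigid_sampled(seq(base), Q,
                                              Mapping.identity(5), 3,
                                              rotation_grid=4)
        # the subset re-superposition finds the exact congruence
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def _exact_rigid_mad(self, P, Q, F, ell):
        best = np.inf
        for sub in itertools.combinations(range(len(F)), ell):
            m = Mapping(tuple(F.pairs[c] for c in sub))
            _, r = superpose(P, Q, m)
            best = min(best, r)
        return best

    def test_never_below_exact_and_close_on_dense_grid(self):
        rng = np.random.default_rng(97531)
        base = rng.normal(size=(5, 3)) * 3
        R0 = random_rotation(rng)
        noisy = base @ R0.T + rng.normal(size=3) + \
            rng.normal(scale=0.6, size=(5, 3))
        P, Q, F = seq(base), seq(noisy), Mapping.identity(5)
        exact = self._exact_rigid_mad(P, Q, F, 3)
        res = mad_given_mapping_rigid_sampled(P, Q, F, 3, rotation_grid=24)
        assert res.rmsd >= exact - 1e-9
        assert res.rmsd <= 1.1 * exact  # 15-degree grid gets within 10%
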