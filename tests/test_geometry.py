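import numpy as np
import pytest
from scipy.stats import special_ortho_group

from bach3d.geometry import (hd_ratio, optimal_superposition,
                             plane_separation_test, sliding_window_rmsd)
from bach3d.poisson_model import Structure3D


def dense_helix(n=2000, height=10.0, radius=1.0, turns=12.0):
    t = np.linspace(0, 2 * np.pi * turns, n)
    z = np.linspace(0, height, n)
    return Structure3D(np.column_stack([radius * np.cos(t),
                                        radius * np.sin(t), z]))


class TestHdRatio:
    def test_uniform_helix_height_diameter(self):
        # height 10, radius 1: 10-90% span = 8, diameter = 4 x median radial
        fit = hd_ratio(dense_helix(), n_ref=25)
        assert fit.hd_raw == pytest.approx(2.0, abs=0.05)

    def test_invariant_under_rigid_motion(self):
        s = dense_helix(n=500)
        r = special_ortho_group.rvs(3, random_state=0)
        moved = Structure3D(s.coords @ r.T + [7, -3, 2])
        assert hd_ratio(moved).hd_raw == pytest.approx(
            hd_ratio(s).hd_raw, abs=1e-9)

    def test_invariant_under_uniform_scaling(self):
        s = dense_helix(n=500)
        scaled = Structure3D(5.0 * s.coords)
        assert hd_ratio(scaled).hd_raw == pytest.approx(
            hd_ratio(s).hd_raw, abs=1e-12)

    def test_size_normalization(self):
        s = dense_helix(n=500)
        fit = hd_ratio(s, n_ref=25)
        assert fit.hd_ratio == pytest.approx(fit.hd_raw / (500 / 25))

    def test_collinear_structure_rejected(self):
        line = Structure3D(np.column_stack([np.arange(10.0),
                                            np.zeros(10), np.zeros(10)]))
        with pytest.raises(ValueError, match="collinear"):
            hd_ratio(line)

    def test_isotropic_cloud_concentrates(self):
        # rotation of the sample must not move the statistic
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(20):
            cloud = rng.normal(size=(400, 3))
            vals.append(hd_ratio(Structure3D(cloud), n_ref=400).hd_ratio)
        vals = np.array(vals)
        assert vals.std() / vals.mean() < 0.15


class TestOptimalSuperposition:
    def test_identical_structures_zero_rmsd(self):
        rng = np.random.default_rng(2)
        s = Structure3D(rng.normal(size=(8, 3)))
        assert optimal_superposition(s, s).rmsd == pytest.approx(0, abs=1e-12)

    def test_scaled_rotated_translated_copy(self):
        rng = np.random.default_rng(3)
        a = Structure3D(rng.normal(size=(8, 3)))
        r = special_ortho_group.rvs(3, random_state=4)
        b = Structure3D(2.0 * a.coords @ r.T + [1, -5, 2])
        res = optimal_superposition(a, b)
        assert res.rmsd < 1e-8
        assert res.scale == pytest.approx(2.0)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a = Structure3D(rng.normal(size=(9, 3)))
        b = Structure3D(rng.normal(size=(9, 3)))
        assert optimal_superposition(a, b).rmsd == pytest.approx(
            optimal_superposition(b, a).rmsd, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rotation_grid_oracle(self, seed):
        """Kabsch result equals a brute-force minimum over a fine
        rotation grid (proper rotations only)."""
        rng = np.random.default_rng(seed)
        a = Structure3D(rng.normal(size=(5, 3)))
        b = Structure3D(rng.normal(size=(5, 3)))
        res = optimal_superposition(a, b)

        ca = a.coords - a.coords.mean(axis=0)
        cb = b.coords - b.coords.mean(axis=0)
        ua = ca / np.sqrt(np.mean(np.sum(ca ** 2, axis=1)))
        ub = cb / np.sqrt(np.mean(np.sum(cb ** 2, axis=1)))

        def rmsd_for(rot):
            resid = ua - ub @ rot.T
            return np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))

        from itertools import product

        def euler_rot(al, be, ga):
            ca_, sa = np.cos(al), np.sin(al)
            cb_, sb = np.cos(be), np.sin(be)
            cg, sg = np.cos(ga), np.sin(ga)
            rz1 = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
            ry = np.array([[cb_, 0, sb], [0, 1, 0], [-sb, 0, cb_]])
            rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
            return rz1 @ ry @ rz2

        # coarse grid over the full rotation group, then local refinement
        best, best_ang = np.inf, (0.0, 0.0, 0.0)
        grid = np.linspace(0, 2 * np.pi, 21, endpoint=False)
        for al, be, ga in product(grid, np.linspace(0, np.pi, 11), grid):
            v = rmsd_for(euler_rot(al, be, ga))
            if v < best:
                best, best_ang = v, (al, be, ga)
        width = 2 * np.pi / 21
        for _ in range(6):
            al0, be0, ga0 = best_ang
            offs = np.linspace(-width, width, 9)
            for da, db, dg in product(offs, offs, offs):
                v = rmsd_for(euler_rot(al0 + da, be0 + db, ga0 + dg))
                if v < best:
                    best, best_ang = v, (al0 + da, be0 + db, ga0 + dg)
            width /= 4.0
        assert res.rmsd <= best + 1e-12
        assert abs(res.rmsd - best) < 1e-3 * max(best, 1.0)


class TestSlidingWindow:
    def test_window_equals_length_gives_one_value(self):
        rng = np.random.default_rng(6)
        a = Structure3D(rng.normal(size=(10, 3)))
        b = Structure3D(rng.normal(size=(10, 3)))
        assert len(sliding_window_rmsd(a, b, window=10)) == 1

    def test_k_minus_nine_values(self):
        rng = np.random.default_rng(7)
        a = Structure3D(rng.normal(size=(19, 3)))
        b = Structure3D(rng.normal(size=(19, 3)))
        assert len(sliding_window_rmsd(a, b, window=10)) == 10

    def test_identical_structures_all_zero(self):
        rng = np.random.default_rng(8)
        a = Structure3D(rng.normal(size=(15, 3)))
        out = sliding_window_rmsd(a, a, window=10)
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_too_short_raises(self):
        rng = np.random.default_rng(9)
        a = Structure3D(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="shorter"):
            sliding_window_rmsd(a, a, window=10)


class TestPlaneSeparation:
    def test_perfectly_separated_groups(self):
        # 6 high at x>0, 6 low at x<0, 3 mid on the x=0 plane:
        # p = 2 / C(12,6) = 2/924
        rng = np.random.default_rng(10)
        hi = np.column_stack([rng.uniform(1, 2, 6),
                              rng.normal(size=6), rng.normal(size=6)])
        lo = np.column_stack([rng.uniform(-2, -1, 6),
                              rng.normal(size=6), rng.normal(size=6)])
        mid = np.array([[0, 0, 0], [0, 1, 0], [0, 0.3, 1.0]])
        coords = np.vstack([hi, lo, mid])
        labels = np.array(["high"] * 6 + ["low"] * 6 + ["mid"] * 3)
        odds, p, table = plane_separation_test(coords, labels)
        assert p == pytest.approx(2 / 924, rel=1e-9)
        # perfect separation: all low on one side, all high on the other
        assert sorted(table[0]) == [0, 6] and sorted(table[1]) == [0, 6]
        assert table[0, 0] != table[1, 0]

    def test_shuffled_labels_not_significant(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(18, 3))
        pvals = []
        for _ in range(100):
            labels = np.array(["high"] * 6 + ["low"] * 6 + ["mid"] * 6)
            rng.shuffle(labels)
            _, p, _ = plane_separation_test(coords, labels)
            pvals.append(p)
        assert np.median(pvals) > 0.1

    def test_degenerate_table_uses_haldane_odds(self):
        rng = np.random.default_rng(12)
        hi = np.column_stack([rng.uniform(1, 2, 4),
                              rng.normal(size=4), rng.normal(size=4)])
        lo = np.column_stack([rng.uniform(0.5, 1, 4),
                              rng.normal(size=4), rng.normal(size=4)])
        mid = np.array([[0, 0, 0], [0, 1, 0], [0, 0.3, 1.0]])
        coords = np.vstack([hi, lo, mid])
        labels = np.array(["high"] * 4 + ["low"] * 4 + ["mid"] * 3)
        odds, p, table = plane_separation_test(coords, labels)
        assert np.isfinite(odds) and odds > 0

    def test_collinear_mid_points_rejected(self):
        coords = np.vstack([np.eye(3), -np.eye(3),
                            [[0, 0, 0], [1, 1, 1], [2, 2, 2]]])
        labels = np.array(["high"] * 3 + ["low"] * 3 + ["mid"] * 3)
        with pytest.raises(ValueError, match="collinear"):
            plane_separation_test(coords, labels)
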