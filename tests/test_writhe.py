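"""Geometry of StS/StA writhe, curvature and density features."""

import numpy as np
import pytest

from writhenet import (RingConformation, global_writhe,
                       local_curvature_profile, local_density_profile,
                       sta_writhe, sts_writhe, total_curvature)
from writhenet.conformation import InvalidGeometryError
from writhenet.fixtures import circle
from writhenet.writhe import raw_sta

from conftest import (figure_eight_curve, gentle_unknot_curve, trefoil_curve,
                      wiggly_unknot_curve)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestPlanarCurves:
    def test_circle_has_zero_writhe_and_flat_profile(self):
        c = circle(100)
        assert abs(global_writhe(c)) < 1e-12
        prof = sta_writhe(c, signed=True)
        assert np.max(np.abs(prof.values)) < 1e-12

    def test_circle_total_curvature_is_two_pi(self):
        # exterior angles of a convex planar polygon sum to exactly 2*pi
        for n in (12, 60, 100):
            assert total_curvature(circle(n)) == pytest.approx(2 * np.pi, abs=1e-9)

    def test_circle_curvature_profile_constant(self):
        c = circle(100)
        prof = local_curvature_profile(c)
        assert np.allclose(prof, 2 * np.pi / 100, atol=1e-9)

    def test_planar_curve_sts_entries_all_zero(self):
        # coplanar segment pairs have vanishing Gauss integrand
        c = circle(64)
        assert np.max(np.abs(sts_writhe(c).values)) < 1e-12

    def test_straight_run_has_zero_interior_curvature(self):
        pos = np.column_stack([np.arange(30.0), np.zeros(30), np.zeros(30)])
        chain = RingConformation(pos, closed=False)
        prof = local_curvature_profile(chain)
        assert np.allclose(prof[1:-1], 0.0, atol=1e-12)


class TestMapStructure:
    def test_exchange_symmetry_and_exclusion_band(self, trefoil200):
        wmap = sts_writhe(trefoil200, exclusion=2)
        v = wmap.values
        assert np.array_equal(v, v.T)
        n = v.shape[0]
        idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        band = np.minimum(idx, n - idx) < 2
        assert np.all(v[band] == 0.0)
        assert np.all(np.isfinite(v))

    def test_mirror_antisymmetry(self, figure_eight200):
        v = sts_writhe(figure_eight200).values
        vm = sts_writhe(figure_eight200.mirror()).values
        assert np.allclose(v, -vm, atol=1e-12)

    def test_mirror_flips_global_writhe_exactly(self, trefoil200):
        assert global_writhe(trefoil200.mirror()) == pytest.approx(
            -global_writhe(trefoil200), abs=1e-12)

    def test_row_sum_identity(self, trefoil200, figure_eight200, wiggly_unknot150):
        # Wr = (1/2) * sum of the unsmoothed signed StA vector
        for curve in (trefoil200, figure_eight200, wiggly_unknot150):
            assert global_writhe(curve) == pytest.approx(
                0.5 * raw_sta(curve).sum(), abs=1e-9)

    def test_sta_is_smoothed_sts_row_sum(self, trefoil200):
        from writhenet.writhe import smooth_profile
        wmap = sts_writhe(trefoil200, window=10.0)
        rows = wmap.values.sum(axis=1)
        w_beads = max(int(round(10.0 / trefoil200.bead_spacing_target)), 1)
        expect = smooth_profile(rows, w_beads, periodic=True)
        got = sta_writhe(trefoil200, window=10.0, signed=True).values
        assert np.allclose(got, expect, atol=0, rtol=0)

    def test_unsigned_dominates_signed(self, figure_eight200):
        s = sta_writhe(figure_eight200, signed=True).values
        u = sta_writhe(figure_eight200, signed=False).values
        assert np.all(u >= np.abs(s) - 1e-12)


class TestQuadratureOracle:
    @pytest.mark.parametrize("fn,fixture_n", [
        (gentle_unknot_curve, 300),
        (trefoil_curve, 400),
        (figure_eight_curve, 400),
    ])
    def test_matches_dense_gauss_integral(self, fn, fixture_n, quadrature_oracle):
        from writhenet.geomutils import resample_closed
        s = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        pos = resample_closed(fn(s), fixture_n)
        lengths = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
        curve = RingConformation(pos, True, float(lengths.mean()))
        expected = quadrature_oracle(fn)
        assert global_writhe(curve) == pytest.approx(expected, abs=1e-2)

    def test_pair_sum_equals_twice_writhe(self, trefoil200):
        wmap = sts_writhe(trefoil200)
        assert wmap.values.sum() == pytest.approx(
            2 * global_writhe(trefoil200), abs=1e-9)


class TestRigidMotionInvariance:
    def test_rotation_translation_leave_writhe_unchanged(self, figure_eight200):
        rot = rotation_matrix([1.0, 2.0, 0.5], 1.1)
        moved = figure_eight200.transformed(rotation=rot,
                                            translation=np.array([5., -3., 2.]))
        assert global_writhe(moved) == pytest.approx(
            global_writhe(figure_eight200), abs=1e-9)
        assert total_curvature(moved) == pytest.approx(
            total_curvature(figure_eight200), abs=1e-9)
        assert np.allclose(sta_writhe(moved).values,
                           sta_writhe(figure_eight200).values, atol=1e-9)


class TestDensityAndErrors:
    def test_compact_globule_denser_than_swollen_coil(self):
        rng = np.random.default_rng(3)
        n = 60
        # compact: random walk folded in a small ball; swollen: circle
        compact = rng.normal(scale=1.5, size=(n, 3))
        compact = compact - compact.mean(axis=0)
        compact_conf = RingConformation(compact, closed=False, validate=False)
        swollen_conf = circle(n)
        d_compact = local_density_profile(compact_conf, radius=2.0).mean()
        d_swollen = local_density_profile(swollen_conf, radius=2.0).mean()
        assert d_compact > d_swollen

    def test_degenerate_geometry_rejected(self):
        pos = circle(50).positions.copy()
        pos[10] = pos[11]
        with pytest.raises(InvalidGeometryError):
            sts_writhe(RingConformation(pos, True, 1.0, validate=False))

    def test_parameter_errors(self):
        c = circle(50)
        with pytest.raises(ValueError):
            sts_writhe(c, exclusion=0)
        with pytest.raises(ValueError):
            sts_writhe(c, exclusion=30)
        with pytest.raises(ValueError):
            global_writhe(RingConformation(c.positions, closed=False,
                                           validate=False))

    def test_fary_milnor_on_parametric_knots(self, trefoil200, figure_eight200):
        assert total_curvature(trefoil200) > 4 * np.pi
        assert total_curvature(figure_eight200) > 4 * np.pi
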