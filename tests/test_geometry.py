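"""Nucleus geometry fits and normalized-radius parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleotopo.geometry import (
    NucleusGeometry,
    build_record,
    fit_geometry,
    normalized_radius,
    nucleolus_surface_distance,
    pair_metrics,
    sector_density,
)


def disk_mask(shape, cx, cy, R):
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= R * R


def ellipse_mask(shape, cx, cy, a, b, theta_deg=0.0):
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    t = math.radians(theta_deg)
    xr = (xx - cx) * math.cos(t) + (yy - cy) * math.sin(t)
    yr = -(xx - cx) * math.sin(t) + (yy - cy) * math.cos(t)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


class TestFitGeometry:
    def test_disk_equivalent_radius(self):
        g = fit_geometry(disk_mask((201, 201), 100, 100, 50), "circle")
        assert g.R == pytest.approx(50, abs=0.5)
        assert g.center[0] == pytest.approx(100, abs=0.1)
        assert g.Sn == pytest.approx(math.pi * 50 * 50, rel=0.01)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 117.0])
    def test_ellipse_moment_fit(self, theta):
        g = fit_geometry(ellipse_mask((221, 221), 110, 110, 60, 40, theta), "ellipse")
        assert 59 <= g.a <= 61
        assert 39 <= g.b <= 41
        dt = abs(g.theta_deg - theta) % 180
        assert min(dt, 180 - dt) < 2.0

    def test_disk_fitted_as_ellipse_is_round(self):
        g = fit_geometry(disk_mask((201, 201), 100, 100, 50), "ellipse")
        assert 1.0 <= g.axis_ratio <= 1.02

    def test_empty_and_degenerate_masks(self):
        with pytest.raises(ValueError):
            fit_geometry(np.zeros((64, 64), bool), "circle")
        line = np.zeros((64, 64), bool)
        line[32, 10:50] = True
        with pytest.raises(ValueError):
            fit_geometry(line, "ellipse")


class TestNormalizedRadius:
    def test_center_boundary_and_midpoint(self):
        c = NucleusGeometry.circle((100, 100), 50)
        assert normalized_radius(c, (100, 100)) == 0.0
        assert normalized_radius(c, (150, 100)) == pytest.approx(1.0)
        e = NucleusGeometry.ellipse((100, 100), 60, 40, 0.0)
        assert normalized_radius(e, (130, 100)) == pytest.approx(0.5)
        assert normalized_radius(e, (100, 140)) == pytest.approx(1.0)

    def test_values_beyond_boundary_not_clamped(self):
        c = NucleusGeometry.circle((0, 0), 10)
        assert normalized_radius(c, (12, 0)) == pytest.approx(1.2)

    def test_ellipse_with_equal_axes_equals_circle(self):
        e = NucleusGeometry.ellipse((50, 50), 30, 30, 77.0)
        c = NucleusGeometry.circle((50, 50), 30)
        for pt in [(60, 40), (50, 79.5), (20.1, 50)]:
            assert normalized_radius(e, pt) == pytest.approx(
                normalized_radius(c, pt), abs=1e-6
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        px=st.floats(-40, 40),
        py=st.floats(-40, 40),
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
        rot=st.floats(0, 360),
        scale=st.floats(0.2, 5.0),
    )
    def test_similarity_invariance_analytic(self, px, py, dx, dy, rot, scale):
        """r is invariant under translation, rotation about the nucleus
        center, and isotropic scaling of mask + point together."""
        c0 = NucleusGeometry.circle((0.0, 0.0), 50.0)
        r0 = normalized_radius(c0, (px, py))
        t = math.radians(rot)
        qx = scale * (px * math.cos(t) - py * math.sin(t)) + dx
        qy = scale * (px * math.sin(t) + py * math.cos(t)) + dy
        c1 = NucleusGeometry.circle((dx, dy), 50.0 * scale)
        assert normalized_radius(c1, (qx, qy)) == pytest.approx(r0, abs=1e-6)

    def test_similarity_invariance_rasterized(self):
        """Same invariance on rasterized masks, looser tolerance."""
        m0 = ellipse_mask((241, 241), 120, 120, 60, 40, 0.0)
        m1 = ellipse_mask((241, 241), 115, 125, 60, 40, 35.0)
        g0, g1 = fit_geometry(m0, "ellipse"), fit_geometry(m1, "ellipse")
        # a point at normalized position (0.5 along major, 0.25 along minor)
        t = math.radians(35.0)
        p0 = (120 + 0.5 * 60, 120 + 0.25 * 40)
        p1 = (115 + 0.5 * 60 * math.cos(t) - 0.25 * 40 * math.sin(t),
              125 + 0.5 * 60 * math.sin(t) + 0.25 * 40 * math.cos(t))
        assert normalized_radius(g1, p1) == pytest.approx(
            normalized_radius(g0, p0), abs=0.02
        )


class TestPairMetrics:
    def test_right_angle(self):
        g = NucleusGeometry.circle((100, 100), 50)
        d, alpha = pair_metrics(g, (125, 100), (100, 125))
        assert alpha == pytest.approx(90.0)

    def test_coincident_centroids(self):
        g = NucleusGeometry.circle((100, 100), 50)
        d, alpha = pair_metrics(g, (120, 110), (120, 110))
        assert d == 0.0
        assert alpha == pytest.approx(0.0, abs=1e-5)

    def test_antipodal_signals(self):
        g = NucleusGeometry.circle((100, 100), 50)
        d, alpha = pair_metrics(g, (130, 100), (70, 100))
        assert d == pytest.approx(1.2)
        assert alpha == pytest.approx(180.0)

    def test_undefined_angle_at_center(self):
        g = NucleusGeometry.circle((100, 100), 50)
        d, alpha = pair_metrics(g, (100, 100), (120, 100))
        assert alpha is None
        assert d == pytest.approx(20 / 50)

    def test_ellipse_normalization_uses_geometric_mean(self):
        g = NucleusGeometry.ellipse((0, 0), 64, 36, 0.0)
        d, _ = pair_metrics(g, (10, 0), (-10, 0))
        assert d == pytest.approx(20 / math.sqrt(64 * 36))


class TestNucleolusDistance:
    def test_inside_is_zero(self):
        boundary = [np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)]
        pixels = [{(x, y) for x in range(11) for y in range(11)}]
        d, _ = nucleolus_surface_distance((5, 5), boundary, pixels)
        assert d == 0.0

    def test_inside_via_convex_hull_when_no_pixel_sets(self):
        boundary = [np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)]
        d, _ = nucleolus_surface_distance((5, 5), boundary, None)
        assert d == 0.0

    def test_distance_to_straight_boundary(self):
        # vertical boundary segment at x=20
        boundary = [np.array([[20, y] for y in range(0, 41)], float)]
        d, dn = nucleolus_surface_distance((10, 20), boundary, [set()], norm_radius=50.0)
        assert d == pytest.approx(10.0, abs=0.71)
        assert dn == pytest.approx(d / 50.0)

    def test_requires_nucleolus(self):
        with pytest.raises(ValueError):
            nucleolus_surface_distance((0, 0), [])


class TestSectorDensity:
    def _record_with_points(self, pts):
        g = NucleusGeometry.circle((0, 0), 50)
        rec = build_record("n0", g)
        from nucleotopo.geometry import SignalFeature

        rec.fish = [SignalFeature("fish", i, p, 10, 0.1, 0.001) for i, p in enumerate(pts)]
        return rec

    def test_one_signal_per_quadrant(self):
        # 45, 135, 225, 315 degrees (counterclockwise, y up)
        s = 30 / math.sqrt(2)
        rec = self._record_with_points([(s, -s), (-s, -s), (-s, s), (s, s)])
        assert sector_density([rec], 4).tolist() == [1, 1, 1, 1]

    def test_all_in_one_sector(self):
        rec = self._record_with_points([(30, -1), (35, -2), (40, -3)])
        counts = sector_density([rec], 8)
        assert counts.sum() == 3 and counts[0] == 3

    def test_isotropic_signals_uniform_over_sectors(self, rng):
        from scipy import stats

        ang = rng.uniform(0, 2 * math.pi, 10_000)
        pts = [(30 * math.cos(a), -30 * math.sin(a)) for a in ang]
        rec = self._record_with_points(pts)
        counts = sector_density([rec], 8)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rejects_single_sector(self):
        with pytest.raises(ValueError):
            sector_density([], 1)


class TestBuildRecord:
    def test_pair_metrics_only_for_two_fish(self):
        class Blob:
            def __init__(self, c, area):
                self.label, self.centroid, self.area_px = 1, c, area
                self.boundary = np.zeros((0, 2))

            def pixel_set(self):
                return set()

        g = NucleusGeometry.circle((100, 100), 50)
        rec2 = build_record("a", g, [Blob((120, 100), 80), Blob((80, 100), 90)])
        assert not rec2.n_fish_flag and rec2.d_norm is not None
        rec3 = build_record("b", g, [Blob((120, 100), 80)] * 3)
        assert rec3.n_fish_flag and rec3.d_norm is None
        assert len(rec3.fish) == 3  # retained, not dropped

    def test_s_norm_sums_below_one(self, control_population):
        spec, nuclei = control_population
        for nuc in nuclei:
            total = sum(s.area_fraction for s in nuc.signals)
            assert total < 1.0
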