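"""Folding index, thickness profiles, shape factor, references, sphericity."""

import math

import numpy as np
import pytest

from cbfold.contour import Contour, ContourError
from cbfold.morphometrics import (
    SEMICIRCLE_SHAPE_FACTOR,
    ThicknessProfile,
    ac_thickness_ratio,
    bulk_modulus_from_acoustics,
    contour_metrics,
    enclosed_area,
    expansion_deviation,
    folding_index,
    reference_expansion,
    shape_factor,
    sphericity,
    thickness_profile,
)
from cbfold.synthetic import gen_ellipsoid_mask, gen_expansion_series

from conftest import circle_contour, polar_contour, semicircle_arc


class TestContourMetrics:
    def test_unit_circle_identities(self):
        m = contour_metrics(circle_contour(n=2000))
        assert m.length == pytest.approx(2 * np.pi, rel=1e-4)
        assert m.area == pytest.approx(np.pi, rel=1e-4)
        np.testing.assert_allclose(m.curvature, 1.0, rtol=1e-3)

    def test_ellipse_area(self):
        theta = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        c = Contour(np.column_stack([2 * np.cos(theta), np.sin(theta)]), closed=True)
        assert contour_metrics(c).area == pytest.approx(2 * np.pi, rel=1e-4)

    def test_area_on_open_contour_errors(self):
        with pytest.raises(ContourError):
            enclosed_area(semicircle_arc())
        assert contour_metrics(semicircle_arc()).area is None


class TestFoldingIndex:
    def test_convex_contours_are_zero(self):
        assert folding_index(circle_contour(), smoothing_scale=0.0) == 0.0
        theta = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        ellipse = Contour(np.column_stack([3 * np.cos(theta), np.sin(theta)]), closed=True)
        assert folding_index(ellipse, smoothing_scale=0.0) == 0.0

    def test_sinusoidal_contour_matches_brute_force(self):
        # independent oracle: analytic polar curvature on a fine grid,
        # arc length integrated where kappa >= 0
        amp, q = 0.2, 6

        def r_f(th):
            return 1.0 + amp * np.sin(q * th)

        th = np.linspace(0, 2 * np.pi, 400_000, endpoint=False)
        r = r_f(th)
        rp = amp * q * np.cos(q * th)
        rpp = -amp * q * q * np.sin(q * th)
        kappa = (r * r + 2 * rp * rp - r * rpp) / (r * r + rp * rp) ** 1.5
        ds = np.sqrt(r * r + rp * rp) * (th[1] - th[0])
        oracle = 100.0 * (1.0 - ds[kappa >= 0].sum() / ds.sum())

        measured = folding_index(polar_contour(r_f, n=20000), smoothing_scale=0.0,
                                 curvature_tolerance=1e-9)
        assert measured == pytest.approx(oracle, abs=0.25)
        assert measured > 5.0  # clearly folded

    def test_zero_amplitude_degenerates_to_circle(self):
        assert folding_index(polar_contour(lambda th: np.ones_like(th)),
                             smoothing_scale=0.0) == 0.0

    def test_smoothing_suppresses_subscale_concavity(self):
        def r_f(th):
            return 100.0 + 0.5 * np.sin(50 * th)  # wiggle period ~12.6 um

        c = polar_contour(r_f, n=8000)
        assert folding_index(c, smoothing_scale=0.0) > 0.0
        assert folding_index(c, smoothing_scale=10.0) == pytest.approx(0.0, abs=1e-6)


class TestThicknessProfile:
    def test_annulus_constant_thickness(self):
        inner = circle_contour(radius=200.0, n=3000)
        outer = circle_contour(radius=215.0, n=3000)
        prof = thickness_profile(inner, outer, spacing=12.5)
        np.testing.assert_allclose(prof.thickness, 15.0, atol=0.02)
        np.testing.assert_allclose(prof.normalized, 1.0, atol=2e-3)

    @pytest.mark.parametrize("spacing", [5.0, 12.5, 40.0])
    def test_annulus_independent_of_spacing(self, spacing):
        inner = circle_contour(radius=200.0, n=3000)
        outer = circle_contour(radius=230.0, n=3000)
        prof = thickness_profile(inner, outer, spacing=spacing)
        assert prof.mean_thickness == pytest.approx(30.0, rel=1e-3)

    def test_sample_count_at_paper_spacing(self):
        # 500 um of inner boundary at 12.5 um spacing -> 40 sample points
        theta = np.linspace(0, 500.0 / 300.0, 2000)
        inner = Contour(np.column_stack([300.0 * np.cos(theta), 300.0 * np.sin(theta)]))
        outer = Contour(np.column_stack([330.0 * np.cos(theta), 330.0 * np.sin(theta)]))
        prof = thickness_profile(inner, outer, spacing=12.5)
        assert len(prof.positions) == 40

    def test_model_section_recovers_amplitude_ratio(self, section_eps03):
        section, gt = section_eps03
        prof = thickness_profile(section.inner_egl, section.outer_egl, spacing=12.5)
        amp = (prof.thickness.max() - prof.thickness.min()) / 2.0
        assert amp / prof.mean_thickness == pytest.approx(gt.derived["at_over_t0"], rel=0.02)

    def test_intersecting_contours_error(self):
        inner = circle_contour(radius=200.0, n=500)
        outer = circle_contour(radius=200.5, n=7)  # coarse heptagon cuts the circle
        with pytest.raises(ContourError):
            thickness_profile(inner, outer)

    def test_spacing_longer_than_contour_errors(self):
        inner = circle_contour(radius=10.0, n=200)
        outer = circle_contour(radius=12.0, n=200)
        with pytest.raises(ContourError):
            thickness_profile(inner, outer, spacing=1e4)


class TestAcThicknessRatio:
    def _profile(self, f):
        pos = np.arange(0.0, 1000.0, 12.5)
        return ThicknessProfile(pos, f(pos), 12.5)

    def test_constant_profile_is_one(self):
        prof = self._profile(lambda s: np.full_like(s, 30.0))
        assert ac_thickness_ratio(prof, 500.0) == pytest.approx(1.0)

    def test_sinusoidal_peak_matches_direct_averaging(self):
        period = 400.0
        f = lambda s: 30.0 * (1.0 + 0.5 * np.cos(2 * np.pi * (s - 500.0) / period))
        prof = self._profile(f)
        ratio = ac_thickness_ratio(prof, 500.0, ac_halfwidth=25.0, flank_extent=200.0)
        pos = prof.positions
        d = np.abs(pos - 500.0)
        oracle = f(pos)[d <= 25.0].mean() / f(pos)[(d > 25.0) & (d <= 200.0)].mean()
        assert ratio == pytest.approx(oracle, rel=1e-12)
        assert ratio > 1.3

    def test_minimum_gives_ratio_below_one(self):
        f = lambda s: 30.0 * (1.0 - 0.4 * np.cos(2 * np.pi * (s - 500.0) / 400.0))
        prof = self._profile(f)
        assert ac_thickness_ratio(prof, 500.0, flank_extent=200.0) < 1.0

    def test_empty_flank_errors(self):
        prof = self._profile(lambda s: np.full_like(s, 30.0))
        with pytest.raises(ValueError):
            ac_thickness_ratio(prof, 500.0, ac_halfwidth=25.0, flank_extent=25.0)


class TestShapeFactor:
    def test_semicircle_any_radius(self):
        for radius in (1.0, 480.0):
            arc = semicircle_arc(radius=radius, n=4001)
            area = np.pi * radius**2 / 2.0
            assert shape_factor(arc, area) == pytest.approx(SEMICIRCLE_SHAPE_FACTOR, rel=1e-5)

    def test_model_shape_eps0_limit(self, section_eps0):
        from cbfold.model import section_shape_factor

        section, _ = section_eps0
        assert section_shape_factor(section) == pytest.approx(SEMICIRCLE_SHAPE_FACTOR, abs=1e-4)

    def test_high_epsilon_exceeds_semicircle_and_converges(self):
        from cbfold.model import model_shape, params_from_epsilon, section_shape_factor, shape_to_section

        params = params_from_epsilon(0.9, phi=-math.pi / 2.0)
        sf = [
            section_shape_factor(shape_to_section(model_shape(params, n_theta=n, domain="half")))
            for n in (1441, 2881)  # doubled resolution as the refinement oracle
        ]
        assert sf[0] > SEMICIRCLE_SHAPE_FACTOR
        assert sf[0] == pytest.approx(sf[1], rel=1e-4)

    def test_nonpositive_area_errors(self):
        with pytest.raises(ValueError):
            shape_factor(semicircle_arc(), 0.0)


class TestReferenceExpansion:
    def test_semicircle_identity(self):
        # A = pi/2 (unit radius) -> L = pi, and L^2 = 2 pi A exactly
        assert reference_expansion(np.pi / 2.0) == pytest.approx(np.pi, rel=1e-15)
        for area in (1.0, 123.4, 2.2e5):
            L = reference_expansion(area)
            assert L * L == pytest.approx(2.0 * np.pi * area, rel=1e-12)

    def test_column_three_sides_convention(self):
        assert reference_expansion(1e4, mode="column", column_width=100.0) == pytest.approx(300.0)
        assert reference_expansion(1e4, mode="column", column_width=100.0,
                                   column_convention="distal_only") == 100.0

    def test_series_on_curve_has_zero_deviation(self):
        series, _ = gen_expansion_series(mode="semicircle", stages=(16.5, 17.5, 18.5))
        np.testing.assert_allclose(expansion_deviation(series), 0.0, atol=1e-14)


class TestSphericity:
    def test_voxelised_sphere_within_2pct(self):
        mask, _ = gen_ellipsoid_mask((20.0, 20.0, 20.0))
        assert sphericity(mask) == pytest.approx(1.0, abs=0.02)

    def test_prolate_spheroid_2_1_1(self):
        mask, gt = gen_ellipsoid_mask((40.0, 20.0, 20.0))
        assert gt.derived["sphericity"] == pytest.approx(0.9287, abs=1e-3)
        assert sphericity(mask) == pytest.approx(gt.derived["sphericity"], rel=0.02)

    def test_monotone_in_aspect_ratio(self):
        values = []
        for a in (20.0, 30.0, 40.0):
            mask, _ = gen_ellipsoid_mask((a, 20.0, 20.0))
            values.append(sphericity(mask))
        assert values[0] > values[1] > values[2]
        assert all(v <= 1.02 for v in values)

    def test_empty_and_split_masks_error(self):
        with pytest.raises(ValueError):
            sphericity(np.zeros((8, 8, 8), dtype=bool))
        two = np.zeros((12, 12, 12), dtype=bool)
        two[2:4, 2:4, 2:4] = True
        two[8:10, 8:10, 8:10] = True
        with pytest.raises(ValueError):
            sphericity(two)


class TestBulkModulus:
    def test_product_and_units(self):
        assert bulk_modulus_from_acoustics(1.5, 1500.0) == pytest.approx(2.25)

    def test_implied_density(self):
        # Z = rho c: Z = 1.5 MRayl at c = 1000 m/s implies rho = 1500 kg/m^3
        Z, c = 1.5, 1000.0
        assert Z * 1e6 / c == pytest.approx(1500.0)

    def test_linearity_and_errors(self):
        assert bulk_modulus_from_acoustics(3.0, 1500.0) == pytest.approx(
            2.0 * bulk_modulus_from_acoustics(1.5, 1500.0)
        )
        with pytest.raises(ValueError):
            bulk_modulus_from_acoustics(-1.0, 1500.0)
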