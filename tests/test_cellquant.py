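"""AC windows, proliferation index and the fiber scan-line pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from cbfold.cellquant import (
    CellRecord,
    FiberImage,
    RegionWindow,
    ac_windows,
    fiber_density_profile,
    proliferation_by_windows,
    proliferation_rate,
)
from cbfold.contour import Contour
from cbfold.synthetic import ac_positions_outer, gen_cells, gen_fiber_image

from conftest import semicircle_arc


def square_window(x0=0.0, y0=0.0, side=100.0, center=50.0):
    poly = Polygon(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )
    return RegionWindow(center=center, width=side, polygon=poly)


def make_cells(n_edu, n_plain, n_p27, edu_p27_overlap=0):
    """Cells on a grid inside the unit square window."""
    cells = []
    total = n_edu + n_plain + n_p27
    xs = np.linspace(5.0, 95.0, max(total, 2))
    for i in range(total):
        edu = i < n_edu or (i >= n_edu + n_plain and i - n_edu - n_plain < edu_p27_overlap)
        p27 = i >= n_edu + n_plain
        cells.append(CellRecord(x=xs[i], y=50.0, edu=bool(edu and not p27), p27=bool(p27)))
    return cells


class TestCellRecord:
    def test_marker_implications(self):
        with pytest.raises(ValueError):
            CellRecord(x=0, y=0, dapi=False, edu=True)
        with pytest.raises(ValueError):
            CellRecord(x=0, y=0, dapi=False, p27=True)


class TestAcWindows:
    def test_default_count_is_21(self):
        arc = semicircle_arc(radius=480.0, n=2001)
        wins = ac_windows(arc, ac_position=arc.arc_length / 2.0)
        assert len(wins) == 21

    def test_zero_extent_single_window(self):
        arc = semicircle_arc(radius=480.0, n=2001)
        wins = ac_windows(arc, ac_position=700.0, extent=0.0)
        assert len(wins) == 1
        assert wins[0].center == 700.0

    def test_adjacent_windows_overlap_by_25um_of_arc(self):
        # 50 um wide windows on 25 um centers share half their arc span
        arc = semicircle_arc(radius=480.0, n=2001)
        wins = ac_windows(arc, ac_position=700.0)
        centers = [w.center for w in wins]
        assert np.allclose(np.diff(centers), 25.0)
        spans = [(w.center - w.width / 2, w.center + w.width / 2) for w in wins]
        overlaps = [s1[1] - s2[0] for s1, s2 in zip(spans, spans[1:])]
        assert np.allclose(overlaps, 25.0)
        inter = wins[0].polygon.intersection(wins[1].polygon).area
        assert inter == pytest.approx(wins[0].polygon.area / 2.0, rel=0.05)

    def test_truncation_flagged_near_contour_end(self):
        arc = semicircle_arc(radius=480.0, n=2001)
        wins = ac_windows(arc, ac_position=100.0)
        assert any(w.truncated for w in wins)
        assert all(w.width > 0 for w in wins)

    def test_extent_must_be_multiple_of_step(self):
        arc = semicircle_arc(radius=480.0, n=2001)
        with pytest.raises(ValueError):
            ac_windows(arc, 700.0, step=25.0, extent=260.0)

    def test_window_depth_stays_inside_tissue(self):
        arc = semicircle_arc(radius=480.0, n=2001)
        (w,) = ac_windows(arc, arc.arc_length / 2.0, extent=0.0, depth=50.0)
        # all polygon points within [430, 480] of the center (depth band)
        d = np.hypot(*np.asarray(w.polygon.exterior.coords).T)
        assert d.max() <= 480.0 + 1e-6
        assert d.min() >= 430.0 - 1.0


class TestProliferationRate:
    def test_simple_ratio(self):
        cells = make_cells(n_edu=30, n_plain=70, n_p27=0)
        assert proliferation_rate(cells, square_window()) == pytest.approx(0.30)

    def test_p27_cells_excluded_from_denominator(self):
        cells = make_cells(n_edu=20, n_plain=30, n_p27=50)
        assert proliferation_rate(cells, square_window()) == pytest.approx(0.40)

    def test_empty_denominator_is_missing_not_zero(self):
        cells = make_cells(n_edu=0, n_plain=0, n_p27=10)
        assert np.isnan(proliferation_rate(cells, square_window()))

    @given(dup=st.integers(min_value=2, max_value=5))
    @settings(max_examples=10, deadline=None)
    def test_invariant_under_duplication(self, dup):
        cells = make_cells(n_edu=13, n_plain=27, n_p27=9)
        rate = proliferation_rate(cells, square_window())
        assert proliferation_rate(cells * dup, square_window()) == pytest.approx(rate)

    def test_binomial_recovery_on_generated_cells(self, section_eps03):
        section, _ = section_eps03
        cells, _ = gen_cells(section, density=12.0, edu_rate=0.35, p27_rate=0.2, seed=7)
        band = RegionWindow(center=0.0, width=1.0, polygon=section.egl_band_polygon())
        eligible = [c for c in cells if not c.p27]
        assert len(eligible) >= 500
        rate = proliferation_rate(cells, band)
        ci = 1.96 * np.sqrt(0.35 * 0.65 / len(eligible))
        assert abs(rate - 0.35) <= ci

    def test_reflection_preserves_rate_multiset(self, section_eps03):
        """Mirroring the section swaps anterior/posterior but the per-window
        rates (as a multiset) are unchanged."""
        section, gt = section_eps03
        cells, _ = gen_cells(section, seed=8)
        s_ac = ac_positions_outer(section, gt)[1]
        wins = ac_windows(section.outer_egl, s_ac, extent=100.0)
        rates = proliferation_by_windows(cells, wins).rate.round(10).tolist()

        flip = lambda pts: np.column_stack([-pts[:, 0], pts[:, 1]])[::-1]
        from cbfold.contour import SectionGeometry

        mirrored = SectionGeometry(
            outer_egl=Contour(flip(section.outer_egl.points)),
            inner_egl=Contour(flip(section.inner_egl.points)),
            base=section.base[::-1] * np.array([-1.0, 1.0]),
            ac_positions=np.sort(section.inner_egl.arc_length - section.ac_positions),
            stage=section.stage,
        )
        m_cells = [
            CellRecord(x=-c.x, y=c.y, edu=c.edu, p27=c.p27, region=c.region) for c in cells
        ]
        m_s_ac = mirrored.outer_egl.arc_length - s_ac
        m_wins = ac_windows(mirrored.outer_egl, m_s_ac, extent=100.0)
        m_rates = proliferation_by_windows(m_cells, m_wins).rate.round(10).tolist()
        def key(v):
            return -1.0 if np.isnan(v) else v
        assert sorted(rates, key=key) == pytest.approx(sorted(m_rates, key=key), nan_ok=True)


class TestFiberPipeline:
    def _flat_image(self, value=1.0, h=160, w=640, pixel=0.5):
        intensity = np.full((h, w), value)
        x = np.arange(0.0, w * pixel, 4.0)
        edge = Contour(np.column_stack([x, np.full_like(x, 4.0)]))
        return FiberImage(intensity=intensity, pixel_size=pixel, egl_outer_edge=edge)

    def test_uniform_image_has_zero_peaks_everywhere(self):
        img = self._flat_image()
        df = fiber_density_profile(img, ac_position=150.0)
        assert (df.count_mean == 0).all()
        assert (df.n_lines == 5).all()

    def test_scanline_offsets_span_five_spacings(self):
        """A horizontal bright stripe at depth k*12.2 um under a flat edge is
        crossed by scan line k alone; a stripe below 5*12.2 um is never seen."""
        for depth, seen in [(2 * 12.2, True), (5 * 12.2 + 8.0, False)]:
            img = self._flat_image()
            row = int((4.0 + depth) / img.pixel_size)
            intensity = img.intensity.copy()
            intensity[row - 1 : row + 2, ::40] = 5.0  # dotted stripe -> peaks
            img2 = FiberImage(intensity=intensity, pixel_size=img.pixel_size,
                              egl_outer_edge=img.egl_outer_edge)
            df = fiber_density_profile(img2, ac_position=150.0)
            assert (df.count_mean.sum() > 0) == seen

    def test_known_crossings_recovered(self, section_eps03):
        section, _ = section_eps03
        counts = [3, 1, 4, 2, 5]
        img, gt = gen_fiber_image(section, counts, seed=2)
        df = fiber_density_profile(img, ac_position=gt.derived["ac_position"])
        centers = gt.derived["bin_start"] + 50.0 * (np.arange(len(counts)) + 0.5)
        got = (
            df.set_index(df.bin_center_um.round(6))
            .loc[np.round(centers, 6), "count_mean"]
            .to_numpy()
        )
        assert np.abs(got - counts).max() <= 1.0

    def test_mean_absolute_error_below_one_across_densities(self, section_eps03):
        section, _ = section_eps03
        errors = []
        for density in range(1, 9):
            img, gt = gen_fiber_image(section, [density] * 5, seed=10 + density)
            df = fiber_density_profile(img, ac_position=gt.derived["ac_position"])
            centers = gt.derived["bin_start"] + 50.0 * (np.arange(5) + 0.5)
            got = (
                df.set_index(df.bin_center_um.round(6))
                .loc[np.round(centers, 6), "count_mean"]
                .to_numpy()
            )
            errors.extend(np.abs(got - density))
        assert np.mean(errors) <= 1.0

    def test_invariant_under_intensity_scaling_and_offset(self, section_eps03):
        section, _ = section_eps03
        img, gt = gen_fiber_image(section, [2, 3, 2], seed=5)
        df1 = fiber_density_profile(img, ac_position=gt.derived["ac_position"])
        scaled = FiberImage(
            intensity=img.intensity * 10.0,
            pixel_size=img.pixel_size,
            egl_outer_edge=img.egl_outer_edge,
        )
        df2 = fiber_density_profile(scaled, ac_position=gt.derived["ac_position"])
        np.testing.assert_allclose(df1.count_mean, df2.count_mean)

    def test_shallow_image_drops_scanlines(self):
        img = self._flat_image(h=70)  # ~35 um tall: deepest lines exit
        with pytest.warns(UserWarning, match="dropped"):
            df = fiber_density_profile(img, ac_position=150.0)
        assert (df.n_lines < 5).all()

    def test_bad_poly_order_rejected(self):
        with pytest.raises(ValueError):
            fiber_density_profile(self._flat_image(), ac_position=150.0, poly_order=3)
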