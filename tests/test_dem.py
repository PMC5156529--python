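"""Gridding, contouring and footprint extraction from elevation rasters."""

import numpy as np
import pytest

from ichnos import (DepthProfile, ElevationGrid, InvalidArgumentError,
                    contour_grid, footprint_template, grid_points,
                    measure_from_dem, rasterize_footprint)
from ichnos.morphometry import Footprint


def _plane_points(coef, n=60, seed=0, extent=100.0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent, size=(n, 2))
    z = coef[0] * xy[:, 0] + coef[1] * xy[:, 1] + coef[2]
    return np.column_stack([xy, z])


class TestGridPoints:
    def test_exact_on_affine_surface(self):
        grid = grid_points(_plane_points((2.0, -1.0, 5.0)), spacing=5.0)
        xs, ys = grid.xy()
        gx, gy = np.meshgrid(xs, ys)
        err = np.nanmax(np.abs(grid.heights - (2.0 * gx - gy + 5.0)))
        assert err < 1e-9

    def test_three_points_blank_outside_triangle(self):
        pts = [(0, 0, 0.0), (100, 0, 1.0), (0, 100, 2.0)]
        grid = grid_points(pts, spacing=10.0)
        assert np.isnan(grid.heights[-1, -1])        # opposite corner: outside hull
        assert np.isfinite(grid.heights[0, 0])
        finite = grid.heights[np.isfinite(grid.heights)]
        # triangulation interpolates, never extrapolates beyond the data range
        assert finite.min() >= 0.0 - 1e-12 and finite.max() <= 2.0 + 1e-12

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(InvalidArgumentError, match="triangulate"):
            grid_points([(0, 0, 1), (1, 1, 2)])
        with pytest.raises(InvalidArgumentError, match="triangulate"):
            grid_points([(i, i, float(i)) for i in range(5)])

    def test_refinement_never_worse_on_smooth_surface(self):
        # fidelity of the gridded representation, judged at a fixed dense
        # evaluation set, must not degrade when the spacing is halved
        from scipy.interpolate import RegularGridInterpolator
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 100, size=(400, 2))
        z = np.sin(xy[:, 0] / 15.0) * np.cos(xy[:, 1] / 20.0) * 10.0
        pts = np.column_stack([xy, z])
        eval_pts = rng.uniform(20, 80, size=(500, 2))
        truth = np.sin(eval_pts[:, 0] / 15.0) * np.cos(eval_pts[:, 1] / 20.0) * 10.0

        def max_err(spacing):
            g = grid_points(pts, spacing=spacing)
            xs, ys = g.xy()
            f = RegularGridInterpolator((ys, xs), g.heights, bounds_error=False)
            vals = f(eval_pts[:, ::-1])
            ok = np.isfinite(vals)
            assert ok.sum() > 400
            return np.max(np.abs(vals[ok] - truth[ok]))

        assert max_err(2.0) <= max_err(4.0) + 1e-9

    def test_ascii_round_trip(self):
        grid = grid_points(_plane_points((0.5, 0.25, 1.0)), spacing=10.0)
        back = ElevationGrid.from_ascii(grid.to_ascii())
        assert back.spacing == grid.spacing
        assert np.allclose(back.heights, grid.heights, atol=1e-4, equal_nan=True)


class TestContours:
    def test_hemispherical_pit_contour_count(self):
        xs = np.arange(-30, 31.0)
        gx, gy = np.meshgrid(xs, xs)
        r = np.hypot(gx, gy)
        depth = 10.0
        z = np.where(r < 25, -depth * np.sqrt(np.clip(1 - (r / 25) ** 2, 0, 1)), 0.0)
        cs = contour_grid(ElevationGrid(origin=(-30, -30), spacing=1.0, heights=z),
                          interval=2.0)
        closed_levels = {lv for lv, xy in cs.polylines
                         if np.allclose(xy[0], xy[-1])}
        assert closed_levels == {-8.0, -6.0, -4.0, -2.0}  # floor(10/2) - 1 interior + rim
        assert len(cs.levels()) in (4, 5)

    def test_tilted_plane_contours_straight_and_parallel(self):
        xs = np.arange(0, 101.0)
        gx, gy = np.meshgrid(xs, xs)
        z = 0.5 * gx
        cs = contour_grid(ElevationGrid(origin=(0, 0), spacing=1.0, heights=z),
                          interval=10.0)
        xs_at_level = []
        for level, xy in cs.polylines:
            assert np.ptp(xy[:, 0]) < 1e-9          # vertical straight line
            xs_at_level.append(xy[0, 0])
        spacings = np.diff(sorted(xs_at_level))
        assert np.allclose(spacings, 20.0)           # 10 / 0.5 apart

    def test_flat_grid_yields_empty_set(self):
        z = np.zeros((20, 20))
        cs = contour_grid(ElevationGrid(origin=(0, 0), spacing=1.0, heights=z),
                          interval=2.0)
        assert cs.polylines == []

    def test_contour_vertices_lie_on_straddling_grid_edges(self):
        # every marching-squares vertex sits on a grid edge whose two end
        # nodes straddle (or touch) the contour level — checked brute force
        rng = np.random.default_rng(5)
        z = rng.normal(0, 3, size=(15, 15))
        from scipy.ndimage import gaussian_filter
        z = gaussian_filter(z, 2.0) * 5
        grid = ElevationGrid(origin=(0, 0), spacing=1.0, heights=z)
        cs = contour_grid(grid, interval=1.0)
        assert cs.polylines
        checked = 0
        for level, xy in cs.polylines:
            for x, y in xy:
                on_col = abs(x - round(x)) < 1e-9
                on_row = abs(y - round(y)) < 1e-9
                assert on_col or on_row
                if on_col and not on_row:
                    j = int(round(x))
                    i0, i1 = int(np.floor(y)), int(np.ceil(y))
                    a, b = z[i0, j], z[i1, j]
                elif on_row and not on_col:
                    i = int(round(y))
                    j0, j1 = int(np.floor(x)), int(np.ceil(x))
                    a, b = z[i, j0], z[i, j1]
                else:
                    continue  # vertex on a node: level equals the node value
                assert (a - level) * (b - level) <= 1e-9
                checked += 1
        assert checked > 100


@pytest.fixture(scope="module")
def template_fp():
    outline, lm = footprint_template(261.0, 104.0, 81.0)
    return Footprint(id="syn", side="right", landmarks=lm, outline=outline)


class TestMeasureFromDem:

    def test_recovers_template_length_and_width(self, template_fp):
        grid = rasterize_footprint(template_fp, spacing=1.0)
        _, m = measure_from_dem(grid, depth_threshold=2.0)
        assert m.length == pytest.approx(261.0, abs=2.0)
        assert m.max_width == pytest.approx(104.0, abs=2.0)

    def test_rotation_invariance(self, template_fp):
        from shapely import affinity
        lm = {k: np.array([[np.cos(np.radians(37)), -np.sin(np.radians(37))],
                           [np.sin(np.radians(37)), np.cos(np.radians(37))]]) @ v
              for k, v in template_fp.landmarks.items()}
        fp = Footprint(id="rot", side="right", landmarks=lm,
                       outline=affinity.rotate(template_fp.outline, 37, origin=(0, 0)))
        grid = rasterize_footprint(fp, spacing=1.0)
        _, m = measure_from_dem(grid, depth_threshold=2.0)
        assert m.length == pytest.approx(261.0, abs=2.5)
        assert m.max_width == pytest.approx(104.0, abs=2.5)

    def test_flat_grid_reports_no_depression(self):
        grid = ElevationGrid(origin=(0, 0), spacing=1.0, heights=np.zeros((50, 50)))
        with pytest.raises(InvalidArgumentError, match="no depression"):
            measure_from_dem(grid)

    def test_two_depressions_rejected(self):
        z = np.zeros((60, 120))
        z[20:40, 10:40] = -5.0
        z[20:40, 70:100] = -5.0
        grid = ElevationGrid(origin=(0, 0), spacing=1.0, heights=z)
        with pytest.raises(InvalidArgumentError, match="2 components"):
            measure_from_dem(grid)

    def test_zero_depth_profile_is_flat(self, template_fp):
        grid = rasterize_footprint(template_fp,
                                   DepthProfile(heel_depth=0.0, toe_depth=0.0))
        with pytest.raises(InvalidArgumentError, match="no depression"):
            measure_from_dem(grid)

    def test_drag_ramp_extends_depression(self, template_fp):
        drag = 100.0
        grid = rasterize_footprint(
            template_fp, DepthProfile(heel_depth=8.0, toe_depth=5.0, drag_length=drag),
            spacing=1.0)
        _, m = measure_from_dem(grid, depth_threshold=2.0)
        expected = 261.0 + drag * (1.0 - 2.0 / 8.0)  # ramp crosses threshold at 2 mm
        assert m.length == pytest.approx(expected, abs=3.0)

    def test_under_resolved_spacing_rejected(self, template_fp):
        with pytest.raises(InvalidArgumentError, match="under-resolved"):
            rasterize_footprint(template_fp, spacing=400.0)

    def test_round_trip_across_random_prints(self):
        # generator -> raster -> extraction recovers the template length
        from ichnos import TrackwayParams, generate_trackway
        rng = np.random.default_rng(11)
        spacing = 2.0
        for seed in rng.integers(0, 2 ** 31, size=10):
            stature = rng.uniform(120, 190)
            params = TrackwayParams(stature=stature, n_footprints=2,
                                    step_sd=0.0, angle_of_gait_sd=0.0,
                                    seed=int(seed))
            tw, truth = generate_trackway(params)
            grid = rasterize_footprint(tw.footprints[0], spacing=spacing)
            _, m = measure_from_dem(grid, depth_threshold=2.0)
            assert m.length == pytest.approx(truth.foot_length, abs=2 * spacing)
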