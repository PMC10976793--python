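"""Terrain layer: generators, slope/aspect, smoothing, Sx, complexity."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orolift import (
    ElevationGrid,
    GridError,
    InvalidParameterError,
    SxConfig,
    blur_elevation,
    blur_sigma,
    compute_slope_aspect,
    gaussian_blur,
    generate_flat,
    generate_gaussian_ridge,
    generate_plane,
    sx_field,
    sx_single_azimuth,
    terrain_complexity,
)
from conftest import oracle_sx_field, oracle_terrain_complexity


class TestElevationGrid:
    def test_validation(self):
        with pytest.raises(GridError):
            ElevationGrid(z=np.zeros(5), dx=10.0)
        with pytest.raises(GridError):
            ElevationGrid(z=np.ones((1, 5)), dx=10.0)
        with pytest.raises(GridError):
            ElevationGrid(z=np.full((4, 4), np.nan), dx=10.0)
        with pytest.raises(InvalidParameterError):
            ElevationGrid(z=np.zeros((4, 4)), dx=0.0)

    def test_cell_map_round_trip_exact(self):
        g = ElevationGrid(z=np.zeros((7, 9)), dx=25.0, origin=(1234.0, 987.0))
        rows, cols = np.meshgrid(np.arange(7), np.arange(9), indexing="ij")
        x, y = g.cell_center(rows, cols)
        r2, c2 = g.fractional_index(x, y)
        assert np.array_equal(r2, rows.astype(float))
        assert np.array_equal(c2, cols.astype(float))


class TestGenerators:
    def test_zero_amplitude_ridge_is_flat(self):
        g = generate_gaussian_ridge((20, 20), 10.0, 0.0, 100.0, base_elevation=7.0)
        assert np.all(g.z == 7.0)

    def test_ridge_azimuth_transpose_symmetry(self):
        g0 = generate_gaussian_ridge((30, 30), 10.0, 50.0, 80.0, ridge_azimuth=0.0)
        g90 = generate_gaussian_ridge((30, 30), 10.0, 50.0, 80.0, ridge_azimuth=90.0)
        np.testing.assert_allclose(g90.z, g0.z.T, atol=1e-12)

    def test_ridge_peak_at_ridge_line(self):
        g = generate_gaussian_ridge((41, 41), 10.0, 100.0, 50.0, base_elevation=5.0)
        assert g.z.max() == pytest.approx(105.0, abs=100.0 * (1 - math.exp(-0.5 * (5.0 / 50.0) ** 2)))

    def test_ridge_max_slope_matches_analytic_gaussian_profile(self):
        # steepest point of the profile is at one width-sigma from the crest,
        # with tan(theta) = peak * exp(-1/2) / sigma
        peak, sigma, dx = 100.0, 200.0, 10.0
        g = generate_gaussian_ridge((201, 201), dx, peak, sigma)
        m = compute_slope_aspect(g)
        expected = math.atan(peak * math.exp(-0.5) / sigma)
        assert m.slope.max() == pytest.approx(expected, rel=1e-3)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            generate_gaussian_ridge((10, 10), 10.0, 100.0, 0.0)
        with pytest.raises(InvalidParameterError):
            generate_gaussian_ridge((10, 10), -1.0, 100.0, 50.0)
        with pytest.raises(InvalidParameterError):
            generate_plane((10, 10), 10.0, -0.5)

    def test_plane_linearity(self):
        g = generate_plane((30, 30), 10.0, 0.1, gradient_azimuth=90.0)
        # two cells 100 m apart east-west differ by exactly 10 m
        assert g.z[10, 20] - g.z[10, 10] == pytest.approx(10.0, abs=1e-12)
        assert np.allclose(np.diff(g.z, axis=0), 0.0)


class TestSlopeAspect:
    def test_flat_grid(self, flat_grid):
        m = compute_slope_aspect(flat_grid)
        assert np.all(m.slope == 0.0)
        assert np.all(m.aspect == 0.0)

    @pytest.mark.parametrize(
        "gradient,azimuth,exp_slope_deg,exp_aspect",
        [
            (0.1, 90.0, math.degrees(math.atan(0.1)), 270.0),   # rises east, faces west
            (1.0, 0.0, 45.0, 180.0),                            # rises north, faces south
            (0.5, 225.0, math.degrees(math.atan(0.5)), 45.0),
        ],
    )
    def test_plane_analytic(self, gradient, azimuth, exp_slope_deg, exp_aspect):
        g = generate_plane((25, 25), 10.0, gradient, gradient_azimuth=azimuth)
        m = compute_slope_aspect(g)
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(np.degrees(m.slope[interior]), exp_slope_deg, atol=1e-9)
        np.testing.assert_allclose(m.aspect[interior], exp_aspect, atol=1e-9)

    def test_slope_range_and_aspect_range(self, random_grid):
        m = compute_slope_aspect(random_grid)
        assert np.all((m.slope >= 0) & (m.slope < np.pi / 2))
        assert np.all((m.aspect >= 0) & (m.aspect < 360))

    def test_rotational_equivariance(self, random_grid):
        m = compute_slope_aspect(random_grid)
        rot = ElevationGrid(z=np.rot90(random_grid.z, -1), dx=random_grid.dx)
        mr = compute_slope_aspect(rot)
        np.testing.assert_allclose(mr.slope, np.rot90(m.slope, -1), atol=1e-12)
        # aspect shifts by +90 degrees (where defined)
        defined = np.rot90(m.slope, -1) > 0
        diff = (mr.aspect - (np.rot90(m.aspect, -1) + 90.0)) % 360.0
        diff = np.minimum(diff, 360.0 - diff)
        assert diff[defined].max() < 1e-9


class TestBlur:
    def test_sigma_schedule(self):
        assert blur_sigma(80.0) == 80.0
        assert blur_sigma(1000.0) == 300.0
        assert blur_sigma(30.0) == 0.8 * 30 + 16
        with pytest.raises(InvalidParameterError):
            blur_sigma(0.0)

    def test_flat_grid_fixed_point(self, flat_grid):
        b = blur_elevation(flat_grid, 80.0)
        np.testing.assert_allclose(b.z, flat_grid.z, atol=1e-12)

    def test_zero_sigma_identity(self, random_grid):
        assert gaussian_blur(random_grid, 0.0) is random_grid

    def test_extrema_bounded_and_mass_preserved(self, random_grid):
        b = blur_elevation(random_grid, 120.0)
        assert b.z.max() <= random_grid.z.max() + 1e-9
        assert b.z.min() >= random_grid.z.min() - 1e-9
        assert b.z.sum() == pytest.approx(random_grid.z.sum(), rel=1e-9)


class TestSx:
    def test_flat_grid_zero(self, flat_grid):
        assert sx_single_azimuth(flat_grid, (10, 10), 45.0) == 0.0
        assert np.all(sx_field(flat_grid, 123.0) == 0.0)

    def test_cell_outside_grid_rejected(self, flat_grid):
        with pytest.raises(GridError):
            sx_single_azimuth(flat_grid, (100, 0), 0.0)

    def test_plane_upslope_ray_gives_arctan_s(self):
        s = 0.2
        g = generate_plane((60, 60), 30.0, s, gradient_azimuth=0.0)  # rises north
        # ray looking north (upslope) from an interior cell: every sample
        # has the same rise/run = s
        val = sx_single_azimuth(g, (40, 30), 0.0, dmax=300.0)
        assert val == pytest.approx(math.atan(s), abs=1e-12)

    def test_hilltop_descending_ray_negative_least_steep(self):
        g = generate_gaussian_ridge((61, 61), 30.0, 80.0, 150.0)
        # from the crest, looking east: strictly descending terrain
        val = sx_single_azimuth(g, (30, 30), 90.0, dmax=500.0)
        z, dx = g.z, g.dx
        angles = [math.atan((z[30, 30 + k] - z[30, 30]) / (k * dx)) for k in range(1, 17)]
        assert val < 0
        assert val == pytest.approx(max(angles), abs=1e-12)

    def test_plane_windward_fan(self):
        s = 0.15
        g = generate_plane((50, 50), 30.0, s, gradient_azimuth=0.0)  # rises north
        # wind from the north blows onto the north-rising slope's south face?
        # the face (downslope) points south (aspect 180); wind from the south
        # (wdir=180) hits the face, and the flipped search looks north, upslope
        sx = sx_field(g, 180.0, SxConfig(dmax=300.0))
        offsets = np.array([-15, -10, -5, 0, 5, 10, 15], dtype=float)
        expected = np.mean(np.arctan(s * np.cos(np.radians(offsets))))
        assert sx[30, 25] == pytest.approx(expected, abs=1e-12)
        assert 0 < sx[30, 25] <= math.atan(s)

    @pytest.mark.parametrize("wdir", [0.0, 137.0, 270.0])
    def test_field_equals_single_azimuth_mean(self, random_grid, wdir):
        cfg = SxConfig()
        sx = sx_field(random_grid, wdir, cfg)
        A = (wdir + 180.0) % 360.0
        cell = (25, 31)
        manual = np.mean([
            sx_single_azimuth(random_grid, cell, A + off, cfg.dmax) for off in cfg.offsets
        ])
        assert sx[cell] == pytest.approx(manual, abs=1e-12)

    def test_matches_brute_force_oracle(self, random_grid):
        sx = sx_field(random_grid, 300.0)
        oracle = oracle_sx_field(random_grid, 300.0)
        np.testing.assert_allclose(sx, oracle, atol=1e-12)

    def test_truncation_mask_marks_edges(self, random_grid):
        sx, mask = sx_field(random_grid, 270.0, return_truncation_mask=True)
        # wind from west -> search east; eastern cells lose samples
        assert mask[:, -1].all()
        assert not mask[:, 0].all() or random_grid.ncols * random_grid.dx < 500


class TestTerrainComplexity:
    def test_flat_zero(self, flat_grid):
        assert np.all(terrain_complexity(flat_grid) == 0.0)

    def test_plane_interior_half(self):
        g = generate_plane((60, 60), 30.0, 0.2, gradient_azimuth=70.0)
        tc = terrain_complexity(g, window=500.0)
        hw = int(round(500.0 / 60.0))
        interior = tc[hw:-hw, hw:-hw]
        np.testing.assert_allclose(interior, 0.5, atol=1e-9)

    def test_spike_window_statistics(self):
        z = np.zeros((41, 41))
        z[20, 20] = 100.0
        g = ElevationGrid(z=z, dx=30.0)
        tc = terrain_complexity(g, window=500.0)
        hw = int(round(500.0 / 60.0))
        n = (2 * hw + 1) ** 2
        assert tc[20, 20] == pytest.approx(1.0 / n, abs=1e-12)

    def test_matches_brute_force_oracle(self, random_grid):
        tc = terrain_complexity(random_grid)
        oracle = oracle_terrain_complexity(random_grid)
        np.testing.assert_allclose(tc, oracle, atol=1e-12)

    def test_range(self, random_grid):
        tc = terrain_complexity(random_grid)
        assert np.all((tc >= 0) & (tc <= 1))

    @given(
        scale=st.floats(0.1, 10.0, allow_nan=False),
        offset=st.floats(-500.0, 500.0, allow_nan=False),
    )
    @settings(max_examples=20, deadline=None)
    def test_affine_elevation_invariance(self, scale, offset):
        rng = np.random.default_rng(7)
        z = rng.normal(0.0, 30.0, (25, 25))
        g1 = ElevationGrid(z=z, dx=30.0)
        g2 = ElevationGrid(z=scale * z + offset, dx=30.0)
        np.testing.assert_allclose(
            terrain_complexity(g1), terrain_complexity(g2), atol=1e-9
        )

    def test_rotational_equivariance(self, random_grid):
        tc = terrain_complexity(random_grid)
        rot = ElevationGrid(z=np.rot90(random_grid.z, -1), dx=random_grid.dx)
        np.testing.assert_allclose(terrain_complexity(rot), np.rot90(tc, -1), atol=1e-12)
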