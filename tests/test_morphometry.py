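"""Morphometry: plane fit, polygon area, LCD, rim-constrained MRW, visibility."""

import dataclasses
import math

import numpy as np
import pytest

from onh import (
    PhantomParams,
    ScanGeometry,
    compute_bmo_area,
    compute_lc_visibility,
    compute_lcd,
    compute_mrw,
    fit_bmo_plane,
    make_phantom_volume,
    measure_volume,
    mrw_point_cloud_oracle,
)
from onh.errors import DegenerateGeometryError, EmptyLCError
from onh.morphometry import (
    ilm_triangles,
    lcd_from_points,
    mrw_from_mesh,
    point_triangle_distance,
)


def ring_xy(n=48, r=900.0, z=0.0):
    t = 2 * math.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.full(n, z)])


def rotation(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = math.radians(deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


class TestPlaneFit:
    def test_coplanar_circle_recovers_plane_exactly(self):
        plane = fit_bmo_plane(ring_xy(z=100.0))
        assert plane.centroid[2] == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.rms_fit_residual == pytest.approx(0.0, abs=1e-9)

    def test_tilted_ellipse_normal_is_exact(self):
        t = 2 * math.pi * np.arange(48) / 48
        pts = np.column_stack([1000 * np.cos(t), 800 * np.sin(t), np.zeros(48)])
        pts = pts @ rotation([1, 0, 0], 10.0).T
        plane = fit_bmo_plane(pts)
        expected = np.array([0.0, -math.sin(math.radians(10)), math.cos(math.radians(10))])
        assert np.allclose(plane.normal, expected, atol=1e-9)

    def test_noisy_ring_recovers_plane_and_residual(self):
        rng = np.random.default_rng(123)
        pts = ring_xy(n=200)
        pts[:, 2] += rng.normal(0.0, 5.0, len(pts))  # perpendicular noise
        plane = fit_bmo_plane(pts)
        angle = math.degrees(math.acos(abs(plane.normal @ np.array([0, 0, 1.0]))))
        assert angle < 1.0
        assert plane.rms_fit_residual == pytest.approx(5.0, rel=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_bmo_plane(np.zeros((2, 3)))
        collinear = np.column_stack([np.arange(10.0), np.arange(10.0), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            fit_bmo_plane(collinear)


class TestBMOArea:
    def test_circle_area_within_polygon_deficit(self):
        ring = ring_xy(n=64)
        plane = fit_bmo_plane(ring)
        area = compute_bmo_area(ring, plane)
        exact = math.pi * 0.9**2
        assert area < exact
        assert area == pytest.approx(exact, rel=2e-3)

    def test_square_area_is_exact(self):
        square = np.array(
            [[0, 0, 0], [1000, 0, 0], [1000, 1000, 0], [0, 1000, 0]], float
        )
        # polygon needs >= 3 pts; plane fit on 4 corners of a square
        plane = fit_bmo_plane(square)
        assert compute_bmo_area(square, plane) == pytest.approx(1.0, abs=1e-12)

    def test_tilted_ellipse_area_matches_analytic(self):
        t = 2 * math.pi * np.arange(96) / 96
        pts = np.column_stack([1000 * np.cos(t), 800 * np.sin(t), np.zeros(96)])
        pts = pts @ rotation([1, 1, 0], 12.0).T + np.array([500.0, -200.0, 80.0])
        plane = fit_bmo_plane(pts)
        assert compute_bmo_area(pts, plane) == pytest.approx(
            math.pi * 1.0 * 0.8, rel=1e-3
        )

    def test_vertex_refinement_converges_at_second_order(self):
        exact = math.pi * 0.9**2
        errors = []
        for n in (16, 32, 64):
            ring = ring_xy(n=n)
            errors.append(exact - compute_bmo_area(ring, fit_bmo_plane(ring)))
        assert errors[0] / errors[1] == pytest.approx(4.0, rel=0.1)
        assert errors[1] / errors[2] == pytest.approx(4.0, rel=0.1)


class TestLCD:
    def test_flat_lc_at_250_um(self):
        volume, _ = make_phantom_volume(PhantomParams(lc_depth=250.0))
        plane = fit_bmo_plane(volume.bmo_points)
        mean_lcd, n = compute_lcd(volume, plane)
        assert mean_lcd == pytest.approx(250.0, abs=1e-9)
        assert n > 0

    def test_lc_coincident_with_plane_is_zero(self):
        volume, _ = make_phantom_volume(PhantomParams(lc_depth=0.0, lc_visible_fraction=1.0))
        plane = fit_bmo_plane(volume.bmo_points)
        mean_lcd, _ = compute_lcd(volume, plane)
        assert mean_lcd == pytest.approx(0.0, abs=1e-9)

    def test_uniform_posterior_shift_moves_mean_exactly(self, default_phantom):
        volume, _ = default_phantom
        plane = fit_bmo_plane(volume.bmo_points)
        base, _ = compute_lcd(volume, plane)
        shifted = dataclasses.replace(volume, lc_height=volume.lc_height + 40.0)
        moved, _ = compute_lcd(shifted, plane)
        assert moved - base == pytest.approx(40.0, abs=1e-9)

    def test_fully_missing_lc_raises(self, default_phantom):
        volume, _ = default_phantom
        empty = dataclasses.replace(volume, lc_height=np.full_like(volume.lc_height, np.nan))
        with pytest.raises(EmptyLCError):
            compute_lcd(empty, fit_bmo_plane(volume.bmo_points))


class TestMRW:
    def test_flat_ilm_gives_rim_height_at_every_point(self):
        # the centroid-based rim admissibility can push a boundary foot
        # inward by at most one grid cell, so per-point equality holds to
        # sub-percent rather than machine precision
        volume, _ = make_phantom_volume(PhantomParams(rim_height=150.0))
        mean_mrw, per_point = compute_mrw(volume)
        assert np.all(per_point >= 150.0 - 1e-9)
        assert np.allclose(per_point, 150.0, rtol=1e-2)
        assert mean_mrw == pytest.approx(150.0, rel=2e-3)

    def test_cupped_ilm_matches_dense_point_cloud_oracle(self):
        params = PhantomParams(rim_height=150.0, cup_depth=400.0, seed=7)
        volume, _ = make_phantom_volume(params)
        mean_mrw, _ = compute_mrw(volume)
        oracle_mean, _ = mrw_point_cloud_oracle(params, factor=10)
        assert mean_mrw == pytest.approx(oracle_mean, rel=5e-3)

    def test_rigid_motion_leaves_mrw_unchanged(self, coarse_geometry):
        volume, _ = make_phantom_volume(PhantomParams(cup_depth=300.0), coarse_geometry)
        tris = ilm_triangles(volume)
        base, per_base = mrw_from_mesh(volume.bmo_points, tris)
        rot = rotation([0.3, -1.0, 0.8], 37.0)
        shift = np.array([123.0, -456.0, 789.0])
        moved = tuple(t @ rot.T + shift for t in tris)
        turned, per_turned = mrw_from_mesh(volume.bmo_points @ rot.T + shift, moved)
        assert turned == pytest.approx(base, rel=1e-9)
        assert np.allclose(per_turned, per_base, rtol=1e-9)

    def test_rigid_motion_leaves_lcd_and_area_unchanged(self, coarse_geometry):
        volume, _ = make_phantom_volume(PhantomParams(bmo_tilt_deg=7.0), coarse_geometry)
        lc_pts = volume.surface_points("lc")
        plane = fit_bmo_plane(volume.bmo_points)
        base_lcd, _ = lcd_from_points(lc_pts, volume.bmo_points, plane)
        base_area = compute_bmo_area(volume.bmo_points, plane)
        rot = rotation([1.0, 2.0, 0.2], -24.0)
        shift = np.array([-50.0, 75.0, 310.0])
        bmo_r = volume.bmo_points @ rot.T + shift
        plane_r = fit_bmo_plane(bmo_r)
        lcd_r, _ = lcd_from_points(lc_pts @ rot.T + shift, bmo_r, plane_r)
        assert lcd_r == pytest.approx(base_lcd, rel=1e-9)
        assert compute_bmo_area(bmo_r, plane_r) == pytest.approx(base_area, rel=1e-9)


class TestPointTriangleDistance:
    def test_matches_trimesh_closest_point(self):
        trimesh = pytest.importorskip("trimesh")
        rng = np.random.default_rng(7)
        vertices = rng.normal(size=(30, 3)) * 100
        faces = rng.integers(0, 30, size=(40, 3))
        faces = faces[(faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])]
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        queries = rng.normal(size=(20, 3)) * 150
        _, ref_dist, _ = trimesh.proximity.closest_point_naive(mesh, queries)
        a, b, c = (vertices[faces[:, k]] for k in range(3))
        ours = np.array([point_triangle_distance(q, a, b, c).min() for q in queries])
        assert np.allclose(ours, ref_dist, rtol=1e-8, atol=1e-8)

    def test_face_edge_vertex_regions(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[1.0, 0.0, 0.0]])
        c = np.array([[0.0, 1.0, 0.0]])
        # above the face
        assert point_triangle_distance(np.array([0.2, 0.2, 5.0]), a, b, c)[0] == pytest.approx(5.0)
        # beyond vertex B
        assert point_triangle_distance(np.array([2.0, 0.0, 0.0]), a, b, c)[0] == pytest.approx(1.0)
        # beyond edge BC
        d = point_triangle_distance(np.array([1.0, 1.0, 0.0]), a, b, c)[0]
        assert d == pytest.approx(math.sqrt(0.5))


class TestVisibility:
    def test_fully_delineated_lc_is_100(self):
        volume, _ = make_phantom_volume(PhantomParams(lc_visible_fraction=1.0))
        plane = fit_bmo_plane(volume.bmo_points)
        assert compute_lc_visibility(volume, plane) == pytest.approx(100.0, abs=0.5)

    def test_ninety_percent_wedge_phantom(self, default_phantom):
        volume, _ = default_phantom
        plane = fit_bmo_plane(volume.bmo_points)
        assert compute_lc_visibility(volume, plane) == pytest.approx(90.0, abs=1.0)

    def test_quarter_wedge_on_circular_bmo(self):
        volume, _ = make_phantom_volume(
            PhantomParams(
                bmo_semi_axis_major=900.0,
                bmo_semi_axis_minor=900.0,
                lc_visible_fraction=0.75,
                seed=5,
            )
        )
        plane = fit_bmo_plane(volume.bmo_points)
        assert compute_lc_visibility(volume, plane) == pytest.approx(75.0, abs=1.0)


class TestMeasureVolume:
    def test_noise_free_phantom_recovers_truth_within_one_percent(self, default_phantom):
        volume, truth = default_phantom
        result = measure_volume(volume)
        assert result.mean_lcd == pytest.approx(truth.true_mean_lcd, rel=0.01)
        assert result.mean_mrw == pytest.approx(truth.true_mean_mrw, rel=0.01)
        assert result.bmo_area == pytest.approx(truth.true_bmo_area, rel=0.01)
        assert result.lc_visibility == pytest.approx(truth.true_lc_visibility, abs=1.0)
        assert result.n_lcd_samples > 0 and result.warnings == ()

    def test_lc_depth_perturbation_moves_only_lcd(self):
        r1 = measure_volume(make_phantom_volume(PhantomParams(lc_depth=250.0))[0])
        r2 = measure_volume(make_phantom_volume(PhantomParams(lc_depth=350.0))[0])
        assert r2.mean_lcd - r1.mean_lcd == pytest.approx(100.0, abs=1.0)
        assert r2.mean_mrw == pytest.approx(r1.mean_mrw, rel=1e-3)
        assert r2.bmo_area == pytest.approx(r1.bmo_area, rel=1e-3)
        assert r2.lc_visibility == pytest.approx(r1.lc_visibility, abs=0.1)

    def test_missing_lc_propagates_empty_lc_error(self, default_phantom):
        volume, _ = default_phantom
        gone = dataclasses.replace(volume, lc_height=np.full_like(volume.lc_height, np.nan))
        with pytest.raises(EmptyLCError):
            measure_volume(gone)

    def test_heavily_missing_ilm_attaches_warning(self, default_phantom):
        volume, _ = default_phantom
        ilm = volume.ilm_height.copy()
        g = volume.geometry
        xs, ys = g.node_grid()
        wx, wy = g.field_extent
        rho = np.hypot((xs - wx / 2) / 950.0, (ys - wy / 2) / 885.0)
        rng = np.random.default_rng(0)
        ilm[(rho < 1.0) & (rng.random(ilm.shape) < 0.4)] = np.nan
        result = measure_volume(dataclasses.replace(volume, ilm_height=ilm))
        assert any("missing" in w for w in result.warnings)

    def test_grid_resolution_stability(self, coarse_geometry):
        fine = ScanGeometry(n_bscans=73, n_ascans=192, bscan_spacing=62.0, ascan_spacing=23.2)
        params = PhantomParams(lc_shape="bowl", cup_depth=250.0)
        r_coarse = measure_volume(make_phantom_volume(params, coarse_geometry)[0])
        r_fine = measure_volume(make_phantom_volume(params, fine)[0])
        assert r_fine.mean_mrw == pytest.approx(r_coarse.mean_mrw, rel=5e-3)
        assert r_fine.mean_lcd == pytest.approx(r_coarse.mean_lcd, rel=5e-3)
        assert r_fine.bmo_area == pytest.approx(r_coarse.bmo_area, rel=5e-3)
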