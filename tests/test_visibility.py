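"""Ray casting, isovists, drift, and the drift field."""

import math

import numpy as np
import pytest
from shapely.geometry import box

import wayvis as wv
from wayvis.building import (
    BuildingParams, Destination, Environment, FloorPlan, Pose, RectOccluder,
)
from wayvis.visibility import ISOVIST_FOV, occluder_segments_2d, _ray_segment_hits

from conftest import fan_area_centroid, make_room_env


def _door_env(occluders=()):
    """An open plane with a 1x2 m door 5 m ahead of the origin."""
    door = Destination("door", 0, "x", 5.0, -0.5, 0.5, 0.0, 2.0, -1,
                       "entrance-forward-facing", "left")
    fl = FloorPlan(box(-20, -20, 20, 20), 0.0, 10.0, box(-20, -20, 20, 20))
    env = Environment("centralized", BuildingParams(), [fl], list(occluders),
                      [], [door], None, Pose(0, 0, 0))
    return env, door


class TestDestinationVisibility:
    def test_destination_behind_pose_is_invisible(self):
        env, door = _door_env()
        pose = Pose(0, 0, 1.0, yaw=180.0)
        s = wv.destination_visibility(pose, door, env,
                                      fov=wv.FieldOfView(90, 60, 100))
        assert s.fraction_visible == 0.0

    def test_unobstructed_centered_door_fully_visible(self):
        env, door = _door_env()
        pose = Pose(0, 0, 1.0, yaw=0.0)
        s = wv.destination_visibility(pose, door, env,
                                      fov=wv.FieldOfView(150, 120, 100))
        assert s.fraction_visible == 1.0
        assert s.n_rays_reaching == s.n_rays_cast == 100

    def test_wall_occluding_lower_half_gives_half_fraction(self):
        # eye at z=1; a mid-way wall up to z=1 blocks exactly the target rows
        # below z=1 on the 10x10 grid (5 of 10 rows)
        wall = RectOccluder("x", 2.5, -5, 5, -1.0, 1.0)
        env, door = _door_env([wall])
        pose = Pose(0, 0, 1.0, yaw=0.0)
        s = wv.destination_visibility(pose, door, env,
                                      fov=wv.FieldOfView(150, 170, 100), n_rays=100)
        assert s.fraction_visible == pytest.approx(0.5)

    def test_viewing_the_back_of_a_door_counts_as_blocked(self):
        env, door = _door_env()
        pose = Pose(10, 0, 1.0, yaw=180.0)  # behind the door plane
        s = wv.destination_visibility(pose, door, env,
                                      fov=wv.FieldOfView(150, 120, 100))
        assert s.fraction_visible == 0.0

    def test_occluder_monotonicity(self):
        env, door = _door_env()
        pose = Pose(0, 0, 1.0, yaw=0.0)
        base = wv.destination_visibility(pose, door, env).fraction_visible
        wall = RectOccluder("x", 2.5, -0.2, 0.2, 0.0, 2.0)
        env2, door2 = _door_env([wall])
        occluded = wv.destination_visibility(pose, door2, env2).fraction_visible
        assert occluded <= base

    def test_ray_count_convergence(self):
        wall = RectOccluder("x", 2.5, -5, 0.1, 0.0, 3.0)
        env, door = _door_env([wall])
        pose = Pose(0, 0, 1.0, yaw=0.0)
        f = [wv.destination_visibility(pose, door, env, n_rays=k * k).fraction_visible
             for k in (100, 137, 173)]
        assert abs(f[1] - f[0]) < 0.01
        assert abs(f[2] - f[1]) < 0.01

    def test_degenerate_door_rejected(self):
        with pytest.raises(ValueError):
            Destination("bad", 0, "x", 5.0, 0.5, 0.5, 0.0, 2.0, -1,
                        "entrance-forward-facing", "left")


class TestIsovist:
    def test_square_room_center_sees_everything(self):
        env = make_room_env(10, 10)
        iso = wv.compute_isovist(np.array([5.0, 5.0, 1.7]), env)
        assert iso.area == pytest.approx(100.0, abs=1e-9)
        assert wv.isovist_drift(iso) == pytest.approx(0.0, abs=1e-9)

    def test_square_room_offset_origin_full_visibility_known_drift(self):
        env = make_room_env(10, 10)
        iso = wv.compute_isovist(np.array([0.5, 0.5, 1.7]), env)
        assert iso.area == pytest.approx(100.0, abs=1e-6)
        # centroid (5,5): drift = sqrt(4.5^2 + 4.5^2)
        assert wv.isovist_drift(iso) == pytest.approx(math.hypot(4.5, 4.5), abs=1e-6)

    def test_l_shaped_isovist_drift_by_rectangle_decomposition(self):
        # 10x4 + 4x6 L-shape as a room with one concave corner column filling
        # the rest of the 10x10 bounding square; origin at the inner corner
        env = make_room_env(10, 10, columns=((4, 4, 10, 10),))
        origin = np.array([4.0 - 1e-9, 4.0 - 1e-9, 1.7])
        iso = wv.compute_isovist(origin, env)
        a1, c1 = 40.0, np.array([5.0, 2.0])   # 10 x 4 rectangle
        a2, c2 = 24.0, np.array([2.0, 7.0])   # 4 x 6 rectangle
        centroid = (a1 * c1 + a2 * c2) / (a1 + a2)
        assert iso.area == pytest.approx(64.0, rel=1e-6)
        assert wv.isovist_drift(iso) == pytest.approx(
            float(np.linalg.norm(centroid - origin[:2])), abs=1e-5)

    def test_column_room_matches_dense_ray_oracle(self):
        env = make_room_env(10, 10, columns=((4, 4, 6, 6),))
        origin = np.array([1.0, 5.0, 1.7])
        iso = wv.compute_isovist(origin, env, angular_resolution=0.5)
        segs = occluder_segments_2d(env, 1.7)
        angles = np.radians(np.arange(-180, 180.0001, 0.01))
        radii = _ray_segment_hits(origin[:2], angles, segs, 100.0)
        area, centroid = fan_area_centroid(origin[:2], angles, radii)
        assert iso.area == pytest.approx(area, rel=0.005)
        drift_oracle = float(np.linalg.norm(centroid - origin[:2]))
        assert wv.isovist_drift(iso) == pytest.approx(drift_oracle, abs=0.05)

    def test_range_monotonicity(self):
        env = make_room_env(60, 60)
        origin = np.array([1.0, 1.0, 1.7])
        areas = [wv.compute_isovist(origin, env,
                                    fov=wv.FieldOfView(360, 180, r)).area
                 for r in (5.0, 20.0, 80.0)]
        assert areas[0] <= areas[1] <= areas[2]

    def test_partial_fov_isovist_contains_origin(self):
        env = make_room_env(10, 10)
        pose = Pose(5, 5, 1.7, yaw=30.0)
        iso = wv.compute_isovist(pose, env, fov=wv.FieldOfView(90, 60, 100))
        assert iso.polygon.buffer(1e-9).contains(
            __import__("shapely.geometry", fromlist=["Point"]).Point(5, 5))
        assert iso.area < 100.0

    def test_origin_off_walkable_rejected(self):
        env = make_room_env(10, 10, columns=((4, 4, 6, 6),))
        with pytest.raises(wv.GeometryError):
            wv.compute_isovist(np.array([5.0, 5.0, 1.7]), env)

    def test_drift_invariant_under_translation_and_quarter_turns(self):
        env = make_room_env(10, 6, columns=((2, 2, 3, 3),))
        origin = np.array([6.0, 4.0, 1.7])
        d0 = wv.isovist_drift(wv.compute_isovist(origin, env))

        # translation by (7, -11)
        def shift_occ(o, dx, dy):
            if o.axis == "x":
                return RectOccluder("x", o.coord + dx, o.umin + dy, o.umax + dy,
                                    o.vmin, o.vmax)
            return RectOccluder("y", o.coord + dy, o.umin + dx, o.umax + dx,
                                o.vmin, o.vmax)

        env_t = make_room_env(10, 6)  # rebuilt below with shifted occluders
        env_t.occluders = [shift_occ(o, 7.0, -11.0) for o in env.occluders]
        d_t = wv.isovist_drift(wv.compute_isovist(
            origin + np.array([7.0, -11.0, 0.0]), env_t, check_origin=False))
        assert d_t == pytest.approx(d0, abs=1e-9)

        # 90-degree rotation (x, y) -> (-y, x)
        def rot_occ(o):
            if o.axis == "x":
                return RectOccluder("y", o.coord, -o.umax, -o.umin, o.vmin, o.vmax)
            return RectOccluder("x", -o.coord, o.umin, o.umax, o.vmin, o.vmax)

        env_r = make_room_env(10, 6)
        env_r.occluders = [rot_occ(o) for o in env.occluders]
        d_r = wv.isovist_drift(wv.compute_isovist(
            np.array([-origin[1], origin[0], 1.7]), env_r, check_origin=False))
        assert d_r == pytest.approx(d0, abs=1e-9)


class TestDriftField:
    def test_symmetric_room_minimum_at_center(self):
        env = make_room_env(11, 11)
        grid = wv.build_nav_grid(env, 1.0, clearance=0.0)
        field = wv.build_drift_field(grid, env)
        vals = field.values[0]
        i, j = np.unravel_index(np.nanargmin(vals), vals.shape)
        assert grid.cell_center((0, int(i), int(j))) == pytest.approx([5.5, 5.5])

    def test_corridor_minimum_on_centerline(self):
        env = make_room_env(20, 2)
        grid = wv.build_nav_grid(env, 0.5, clearance=0.0)
        field = wv.build_drift_field(grid, env)
        vals = field.values[0]
        # minimal drift cells sit on the corridor's long centre-line (y=1)
        i, j = np.unravel_index(np.nanargmin(vals), vals.shape)
        assert grid.cell_center((0, int(i), int(j)))[1] == pytest.approx(1.0, abs=0.3)

    def test_field_equals_per_cell_composition(self):
        env = make_room_env(3, 3, columns=((1, 0, 2, 1),))
        grid = wv.build_nav_grid(env, 1.0, clearance=0.0)
        field = wv.build_drift_field(grid, env)
        for cell in grid.walkable_cells(0):
            c = grid.cell_center(cell)
            iso = wv.compute_isovist(np.array([c[0], c[1], 1.7]), env,
                                     angular_resolution=2.0, check_origin=False)
            assert field.drift_at(cell) == pytest.approx(wv.isovist_drift(iso),
                                                         abs=1e-12)

    def test_unwalkable_cell_query_rejected(self):
        env = make_room_env(10, 10, columns=((4, 4, 6, 6),))
        grid = wv.build_nav_grid(env, 1.0, clearance=0.0)
        field = wv.build_drift_field(grid, env)
        with pytest.raises(wv.GeometryError):
            field.drift_at((0, 4, 4))  # centre (4.5, 4.5) is inside the column
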