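"""Shared fixtures: the two study buildings, navigation products, toy rooms."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

import wayvis as wv
from wayvis.building import BuildingParams, Environment, FloorPlan, Pose, RectOccluder


@pytest.fixture(scope="session")
def env_centralized() -> Environment:
    return wv.build_building("centralized")


@pytest.fixture(scope="session")
def env_distributed() -> Environment:
    return wv.build_building("distributed")


@pytest.fixture(scope="session")
def nav_grid(env_centralized):
    return wv.build_nav_grid(env_centralized, 1.0)


@pytest.fixture(scope="session")
def drift_field(env_centralized, nav_grid):
    return wv.build_drift_field(nav_grid, env_centralized)


@pytest.fixture(scope="session")
def zones(env_centralized):
    return wv.decompose_zones(env_centralized)


@pytest.fixture(scope="session")
def world(env_centralized, nav_grid, zones, drift_field):
    return wv.AgentWorld(env_centralized, nav_grid, zones, drift_field)


def make_room_env(width: float, height: float,
                  columns: tuple[tuple[float, float, float, float], ...] = (),
                  wall_height: float = 3.0,
                  escalator=None) -> Environment:
    """A single-floor rectangular room with optional rectangular columns.

    Columns are (x0, y0, x1, y1) boxes: opaque to rays and cut from the
    walkable polygon.
    """
    walk = box(0, 0, width, height)
    occ = [
        RectOccluder("x", 0.0, 0.0, height, 0.0, wall_height),
        RectOccluder("x", width, 0.0, height, 0.0, wall_height),
        RectOccluder("y", 0.0, 0.0, width, 0.0, wall_height),
        RectOccluder("y", height, 0.0, width, 0.0, wall_height),
    ]
    for (x0, y0, x1, y1) in columns:
        walk = walk.difference(box(x0, y0, x1, y1))
        occ += [
            RectOccluder("x", x0, y0, y1, 0.0, wall_height),
            RectOccluder("x", x1, y0, y1, 0.0, wall_height),
            RectOccluder("y", y0, x0, x1, 0.0, wall_height),
            RectOccluder("y", y1, x0, x1, 0.0, wall_height),
        ]
    fl = FloorPlan(footprint=box(0, 0, width, height), elevation=0.0,
                   ceiling_height=wall_height, walkable=walk)
    return Environment(
        atria_type="centralized", params=BuildingParams(), floors=[fl],
        occluders=occ, atria=[], destinations=[], escalator=escalator,
        entrance=Pose(0.5, 0.5, 0.0),
    )


def fan_area_centroid(origin: np.ndarray, angles: np.ndarray,
                      radii: np.ndarray) -> tuple[float, np.ndarray]:
    """Independent shadow-accumulation oracle: area and centroid of a ray fan.

    Each consecutive ray pair spans a triangle (origin, p_i, p_{i+1}); areas
    and centroids accumulate additively.  Used to cross-check polygon-based
    isovist area/centroid at dense angular resolution.
    """
    pts = origin[None, :] + np.column_stack([radii * np.cos(angles),
                                             radii * np.sin(angles)])
    a_tot = 0.0
    c_tot = np.zeros(2)
    for i in range(len(pts) - 1):
        p, q = pts[i], pts[i + 1]
        a = 0.5 * abs((p[0] - origin[0]) * (q[1] - origin[1])
                      - (q[0] - origin[0]) * (p[1] - origin[1]))
        c = (origin + p + q) / 3.0
        a_tot += a
        c_tot += a * c
    return a_tot, c_tot / max(a_tot, 1e-300)
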