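"""Visibility computation: ray casting, isovists, and drift fields.

Destination visibility follows the study's post-processing definition: a
uniform grid of rays is cast from the eye to points on the destination door
surface, clipped by the camera field of view, and the visible fraction is the
share of rays that reach the door unoccluded.  Exploration guidance uses 2D
isovists (the polygon visible from a vantage point in a horizontal slice at
eye height) and their *drift* — the distance from the vantage point to the
isovist polygon's area centroid, which is minimal at the centres of spaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .building import (
    Destination,
    Environment,
    GeometryError,
    NavGrid,
    Pose,
    RectOccluder,
    _AXIS_INDEX,
    _UV_AXES,
    normalize_yaw,
)


@dataclass(frozen=True)
class FieldOfView:
    """A symmetric view cone: horizontal/vertical full angles and a range."""

    horizontal_angle: float = 150.0
    vertical_angle: float = 60.0
    view_range: float = 100.0

    def __post_init__(self) -> None:
        for a in (self.horizontal_angle, self.vertical_angle):
            if not 0.0 < a <= 360.0:
                raise ValueError("FOV angles must lie in (0, 360]")
        if self.view_range <= 0:
            raise ValueError("view_range must be positive")


#: 360-degree isovist cast used for the drift measure.
ISOVIST_FOV = FieldOfView(horizontal_angle=360.0, vertical_angle=180.0, view_range=100.0)

#: Default desktop-camera FOV used when scoring human destination visibility
#: (16:9 monitor with a 60 degree vertical camera angle).
HUMAN_FOV = FieldOfView(horizontal_angle=91.0, vertical_angle=60.0, view_range=100.0)


@dataclass(frozen=True)
class VisibilitySample:
    fraction_visible: float
    n_rays_cast: int
    n_rays_reaching: int


@dataclass
class Isovist:
    origin: np.ndarray  # 3D cast point (eye height)
    polygon: Polygon

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


# ---------------------------------------------------------------------------
# Ray / occluder intersection
# ---------------------------------------------------------------------------

def rays_blocked(origins: np.ndarray, targets: np.ndarray,
                 occluders: list[RectOccluder]) -> np.ndarray:
    """Boolean mask: segment origin->target intersects an opaque rectangle.

    ``origins`` and ``targets`` are (N, 3); endpoints lying exactly on an
    occluder plane (e.g. a door embedded in its wall) do not count as hits.
    """
    origins = np.atleast_2d(origins).astype(float)
    targets = np.atleast_2d(targets).astype(float)
    d = targets - origins
    blocked = np.zeros(len(origins), dtype=bool)
    for occ in occluders:
        ax = _AXIS_INDEX[occ.axis]
        denom = d[:, ax]
        live = ~blocked & (np.abs(denom) > 1e-12)
        if not live.any():
            continue
        t = np.empty(len(origins))
        t[live] = (occ.coord - origins[live, ax]) / denom[live]
        hit = live & (t > 1e-9) & (t < 1.0 - 1e-9)
        if not hit.any():
            continue
        ua, va = (_AXIS_INDEX[a] for a in _UV_AXES[occ.axis])
        pu = origins[hit, ua] + t[hit] * d[hit, ua]
        pv = origins[hit, va] + t[hit] * d[hit, va]
        blocked[np.nonzero(hit)[0][occ.contains_uv(pu, pv)]] = True
    return blocked


def _fov_mask(pose: Pose, targets: np.ndarray, fov: FieldOfView) -> np.ndarray:
    """Targets inside the yaw/pitch-oriented view cone and within range."""
    d = targets - pose.xyz[None, :]
    dist = np.linalg.norm(d, axis=1)
    horiz = np.hypot(d[:, 0], d[:, 1])
    az = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    d_az = np.abs((az - pose.yaw + 180.0) % 360.0 - 180.0)
    el = np.degrees(np.arctan2(d[:, 2], horiz))
    d_el = np.abs(el - pose.pitch)
    return (
        (dist <= fov.view_range)
        & (d_az <= fov.horizontal_angle / 2.0 + 1e-12)
        & (d_el <= fov.vertical_angle / 2.0 + 1e-12)
    )


def destination_visibility(pose: Pose, dest: Destination, env: Environment,
                           fov: FieldOfView = HUMAN_FOV,
                           n_rays: int = 100) -> VisibilitySample:
    """Fraction of a uniform ray grid reaching the destination surface.

    Rays are clipped by the field of view; rays approaching the back of the
    door count as blocked (the door face is one-sided).
    """
    targets = dest.target_points(n_rays)
    n = len(targets)
    ok = _fov_mask(pose, targets, fov)
    # one-sided door: the eye must sit on the door's front side
    front = (pose.xyz[_AXIS_INDEX[dest.axis]] - dest.coord) * dest.front > 0
    if front and ok.any():
        idx = np.nonzero(ok)[0]
        blocked = rays_blocked(np.repeat(pose.xyz[None, :], len(idx), axis=0),
                               targets[idx], env.occluders)
        ok[idx[blocked]] = False
    elif not front:
        ok[:] = False
    reaching = int(ok.sum())
    return VisibilitySample(fraction_visible=reaching / n,
                            n_rays_cast=n, n_rays_reaching=reaching)


def visibility_fractions(eyes: np.ndarray, dest: Destination, env: Environment,
                         fov: FieldOfView, yaws: np.ndarray, pitches: np.ndarray,
                         n_rays: int = 100) -> np.ndarray:
    """Vectorised destination visibility for many poses of one trajectory."""
    targets = dest.target_points(n_rays)
    m = len(targets)
    eyes = np.atleast_2d(eyes)
    n = len(eyes)
    # pose-target geometry, broadcast (n, m)
    d = targets[None, :, :] - eyes[:, None, :]
    dist = np.linalg.norm(d, axis=2)
    horiz = np.hypot(d[:, :, 0], d[:, :, 1])
    az = np.degrees(np.arctan2(d[:, :, 1], d[:, :, 0]))
    d_az = np.abs((az - yaws[:, None] + 180.0) % 360.0 - 180.0)
    el = np.degrees(np.arctan2(d[:, :, 2], horiz))
    d_el = np.abs(el - pitches[:, None])
    ok = ((dist <= fov.view_range)
          & (d_az <= fov.horizontal_angle / 2.0 + 1e-12)
          & (d_el <= fov.vertical_angle / 2.0 + 1e-12))
    front = (eyes[:, _AXIS_INDEX[dest.axis]] - dest.coord) * dest.front > 0
    ok &= front[:, None]
    flat = np.nonzero(ok.ravel())[0]
    if len(flat):
        o = np.repeat(eyes, m, axis=0)[flat]
        t = np.tile(targets, (n, 1))[flat]
        blocked = rays_blocked(o, t, env.occluders)
        okf = ok.ravel()
        okf[flat[blocked]] = False
        ok = okf.reshape(n, m)
    return ok.sum(axis=1) / m


# ---------------------------------------------------------------------------
# Isovists
# ---------------------------------------------------------------------------

def occluder_segments_2d(env: Environment, z: float) -> np.ndarray:
    """(S, 4) horizontal wall segments (x0, y0, x1, y1) crossing height z.

    Vertical occluders whose height band straddles ``z`` bound the isovist
    slice; glass-door holes are treated as bounding surfaces too (glass still
    delimits the visible volume even though destination rays pass through it).
    """
    segs = []
    for occ in env.occluders:
        if occ.axis == "z" or not (occ.vmin < z < occ.vmax):
            continue
        if occ.axis == "x":
            segs.append((occ.coord, occ.umin, occ.coord, occ.umax))
        else:
            segs.append((occ.umin, occ.coord, occ.umax, occ.coord))
    return np.asarray(segs, dtype=float).reshape(-1, 4)


def _ray_segment_hits(origin: np.ndarray, angles: np.ndarray,
                      segs: np.ndarray, view_range: float) -> np.ndarray:
    """Distance to the nearest segment per ray angle (capped at view_range)."""
    ca, sa = np.cos(angles), np.sin(angles)
    r = np.full(len(angles), view_range)
    if len(segs) == 0:
        return r
    p0 = segs[:, 0:2]
    e = segs[:, 2:4] - p0
    w = p0 - origin[None, :]
    # solve origin + t*d = p0 + s*e : cross products, broadcast (A, S)
    denom = ca[:, None] * e[None, :, 1] - sa[:, None] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]) / denom
        s = (w[None, :, 0] * sa[:, None] - w[None, :, 1] * ca[:, None]) / denom
    valid = (np.abs(denom) > 1e-14) & (t > 1e-9) & (s >= -1e-12) & (s <= 1 + 1e-12)
    t = np.where(valid, t, np.inf)
    return np.minimum(r, t.min(axis=1))


def compute_isovist(origin: np.ndarray | Pose, env: Environment,
                    fov: FieldOfView = ISOVIST_FOV,
                    angular_resolution: float = 1.0,
                    check_origin: bool = True) -> Isovist:
    """Cast a 2D isovist from a 3D point (eye height) in a horizontal slice.

    The boundary polygon is traced by an angular sweep augmented with rays
    aimed just past every wall endpoint, so polygonal scenes are recovered
    essentially exactly; the view-range circle is discretised at the sweep
    resolution.
    """
    if angular_resolution <= 0:
        raise ValueError("angular_resolution must be positive")
    if isinstance(origin, Pose):
        yaw = origin.yaw
        origin = origin.xyz
    else:
        origin = np.asarray(origin, dtype=float)
        yaw = 0.0
    z = float(origin[2])
    o2 = origin[:2]
    if check_origin:
        fi = env.floor_at_z(z)
        fl = env.floors[fi]
        if not fl.walkable.buffer(1e-6).covers(Point(o2)):
            raise GeometryError("isovist origin is not on a walkable location")
    segs = occluder_segments_2d(env, z)

    full = fov.horizontal_angle >= 360.0 - 1e-9
    if full:
        a0, a1 = -math.pi, math.pi
    else:
        half = math.radians(fov.horizontal_angle / 2.0)
        a0, a1 = math.radians(yaw) - half, math.radians(yaw) + half
    base = np.arange(a0, a1, math.radians(angular_resolution))
    extra = []
    eps = 1e-7
    for seg in segs:
        for px, py in ((seg[0], seg[1]), (seg[2], seg[3])):
            ang = math.atan2(py - o2[1], px - o2[0])
            for cand in (ang - eps, ang, ang + eps):
                extra.append(cand)
    angles = np.concatenate([base, np.asarray(extra)]) if extra else base
    if full:
        angles = (angles + math.pi) % (2 * math.pi) - math.pi
    else:
        angles = angles[(angles >= a0 - 1e-12) & (angles <= a1 + 1e-12)]
        angles = np.concatenate([[a0], angles, [a1]])
    angles = np.unique(angles)
    r = _ray_segment_hits(o2, angles, segs, fov.view_range)
    pts = o2[None, :] + np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    if not full:
        pts = np.vstack([o2, pts, o2])
    if len(pts) < 3:
        raise GeometryError("isovist degenerated to fewer than 3 points")
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return Isovist(origin=origin, polygon=poly)


def isovist_drift(iso: Isovist) -> float:
    """Distance (m) from the cast point to the isovist polygon centroid."""
    return float(np.linalg.norm(iso.centroid - iso.origin[:2]))


@dataclass
class DriftField:
    """Pre-computed drift per walkable navigation cell (NaN elsewhere)."""

    grid: NavGrid
    values: list[np.ndarray]  # one (nx, ny) array per floor

    def drift_at(self, cell: tuple[int, int, int]) -> float:
        f, i, j = cell
        v = self.values[f][i, j]
        if np.isnan(v):
            raise GeometryError(f"cell {cell} is not walkable")
        return float(v)

    def floor_values(self, floor: int) -> np.ndarray:
        """Drift for walkable cells of one floor, in ``cell_centers`` order."""
        fg = self.grid.floors[floor]
        return self.values[floor][fg.walkable]

    def to_raster_rows(self, floor: int) -> np.ndarray:
        return self.values[floor]


def build_drift_field(grid: NavGrid, env: Environment,
                      eye_height: float | None = None,
                      angular_resolution: float = 2.0) -> DriftField:
    """Cast a 360-degree isovist from every walkable cell and store its drift.

    Isovists are cast at eye height (default the building's 1.7 m) above each
    floor's elevation.
    """
    eye = env.params.eye_height if eye_height is None else eye_height
    values = []
    for f, fg in enumerate(grid.floors):
        z = fg.elevation + eye
        vals = np.full((fg.nx, fg.ny), np.nan)
        ii, jj = np.nonzero(fg.walkable)
        for i, j in zip(ii, jj):
            c = grid.cell_center((f, int(i), int(j)))
            iso = compute_isovist(np.array([c[0], c[1], z]), env,
                                  angular_resolution=angular_resolution,
                                  check_origin=False)
            vals[i, j] = isovist_drift(iso)
        values.append(vals)
    return DriftField(grid=grid, values=values)
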