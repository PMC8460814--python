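"""Parametric multilevel study buildings.

Two two-storey buildings are generated that differ only in the layout of the
atria voids cut from the second-floor slab: a *centralized* variant with a
single 288 m^2 atrium and a *distributed* variant with three atria totalling
the same 288 m^2.  The first floor is a rectangular hall ringed by enclosed
perimeter rooms; an escalator connects the hall to a fenced perimeter walkway
on the second floor.  Eight destination doors (four per floor, two
entrance-forward-facing and two entrance-backwards-facing per floor) are
embedded in the room walls.

Coordinate convention: right-handed, z-up, metres.  The origin sits at the
building entrance and the fixed initial heading points along +x.  Yaw is
measured in degrees counterclockwise from +x, pitch in degrees upward from
the horizontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx
from shapely.geometry import LineString, Polygon, box
from shapely.ops import split as shapely_split
from shapely import contains_xy

ATRIA_TYPES = ("centralized", "distributed")

# Axis pairs spanned by an axis-aligned rectangle perpendicular to `axis`.
_UV_AXES = {"x": ("y", "z"), "y": ("x", "z"), "z": ("x", "y")}
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def normalize_yaw(yaw: float) -> float:
    """Wrap a heading angle into [-180, 180) degrees."""
    return float((yaw + 180.0) % 360.0 - 180.0)


@dataclass
class Pose:
    """A position plus camera orientation (degrees)."""

    x: float
    y: float
    z: float
    yaw: float = 0.0
    pitch: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.pitch <= 90.0:
            raise ValueError(f"pitch must lie in [-90, 90], got {self.pitch}")
        self.yaw = normalize_yaw(self.yaw)

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def heading_vector(self) -> np.ndarray:
        """Unit camera-forward vector implied by yaw and pitch."""
        yaw = math.radians(self.yaw)
        pitch = math.radians(self.pitch)
        return np.array(
            [
                math.cos(pitch) * math.cos(yaw),
                math.cos(pitch) * math.sin(yaw),
                math.sin(pitch),
            ]
        )


@dataclass(frozen=True)
class RectOccluder:
    """Axis-aligned opaque rectangle, optionally pierced by rectangular holes.

    ``axis`` names the normal direction; the rectangle spans
    ``[umin, umax] x [vmin, vmax]`` in the two remaining axes (in x, y, z
    order).  Holes (e.g. glass doors, atria voids) are transparent to rays.
    """

    axis: str
    coord: float
    umin: float
    umax: float
    vmin: float
    vmax: float
    holes: tuple[tuple[float, float, float, float], ...] = ()
    kind: str = "wall"

    def __post_init__(self) -> None:
        if self.axis not in _UV_AXES:
            raise ValueError(f"axis must be one of x/y/z, got {self.axis!r}")
        if self.umax <= self.umin or self.vmax <= self.vmin:
            raise ValueError("degenerate occluder extent")

    def contains_uv(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Boolean mask: (u, v) lies on the opaque part of the rectangle."""
        inside = (u >= self.umin) & (u <= self.umax) & (v >= self.vmin) & (v <= self.vmax)
        for hu0, hu1, hv0, hv1 in self.holes:
            inside &= ~((u > hu0) & (u < hu1) & (v > hv0) & (v < hv1))
        return inside


@dataclass(frozen=True)
class Destination:
    """A destination door: a vertical axis-aligned rectangle in a wall.

    ``front`` is +1 or -1: the door face is visible from positions with
    coordinate-along-axis on that side of the wall plane.
    """

    id: str
    floor: int
    axis: str  # "x" or "y": normal of the door plane
    coord: float
    umin: float
    umax: float
    zmin: float
    zmax: float
    front: int
    facing: str  # "entrance-forward-facing" | "entrance-backwards-facing"
    side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError("door plane must be vertical (axis x or y)")
        if self.umax <= self.umin or self.zmax <= self.zmin:
            raise ValueError(f"degenerate (zero-area) destination surface: {self.id}")
        if self.front not in (-1, 1):
            raise ValueError("front must be +1 or -1")

    @property
    def area(self) -> float:
        return (self.umax - self.umin) * (self.zmax - self.zmin)

    @property
    def center(self) -> np.ndarray:
        u = 0.5 * (self.umin + self.umax)
        z = 0.5 * (self.zmin + self.zmax)
        if self.axis == "x":
            return np.array([self.coord, u, z])
        return np.array([u, self.coord, z])

    def target_points(self, n_rays: int) -> np.ndarray:
        """Uniform k x k grid of ray targets over the door surface.

        k is the largest integer with k*k <= n_rays; targets sit at cell
        centres of the grid so no target lies exactly on the door edge.
        """
        if n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        k = max(1, int(math.isqrt(n_rays)))
        us = self.umin + (np.arange(k) + 0.5) * (self.umax - self.umin) / k
        zs = self.zmin + (np.arange(k) + 0.5) * (self.zmax - self.zmin) / k
        uu, zz = np.meshgrid(us, zs)
        pts = np.empty((k * k, 3))
        if self.axis == "x":
            pts[:, 0] = self.coord
            pts[:, 1] = uu.ravel()
        else:
            pts[:, 0] = uu.ravel()
            pts[:, 1] = self.coord
        pts[:, 2] = zz.ravel()
        return pts

    def approach_point(self, offset: float = 0.6) -> np.ndarray:
        """Ground point just in front of the door (walk target)."""
        c = self.center.copy()
        c[_AXIS_INDEX[self.axis]] += self.front * offset
        c[2] = 0.0
        return c


@dataclass(frozen=True)
class Escalator:
    """Single straight escalator ramp between the two floors."""

    base: tuple[float, float, float]
    top: tuple[float, float, float]

    @property
    def base_xy(self) -> np.ndarray:
        return np.asarray(self.base[:2], dtype=float)

    @property
    def top_xy(self) -> np.ndarray:
        return np.asarray(self.top[:2], dtype=float)

    @property
    def polyline(self) -> np.ndarray:
        return np.array([self.base, self.top], dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.top) - np.asarray(self.base)))


@dataclass
class FloorPlan:
    footprint: Polygon
    elevation: float
    ceiling_height: float
    walkable: Polygon
    rooms: list[Polygon] = field(default_factory=list)


@dataclass
class BuildingParams:
    """Every dimension of the parametric building (metres).

    Only the total atria area is constrained by the study design; all other
    dimensions are reasonable defaults for a 36 m x 18 m two-storey hall and
    may be overridden.
    """

    length: float = 36.0
    width: float = 18.0
    floor_height: float = 3.0
    ceiling_height: float = 3.0
    room_depth: float = 3.0
    atria_total_area: float = 288.0
    fence_x: tuple[float, float] = (5.5, 32.5)
    fence_y: tuple[float, float] = (-6.5, 6.5)
    fence_height: float = 1.0
    door_width: float = 1.0
    door_height: float = 2.0
    eye_height: float = 1.7
    escalator_base: tuple[float, float] = (9.3, -4.5)
    escalator_top: tuple[float, float] = (3.3, -4.5)
    escalator_width: float = 1.5
    entrance_x: float = 1.0

    def validate(self) -> None:
        for name in ("length", "width", "floor_height", "ceiling_height", "room_depth",
                     "door_width", "door_height", "eye_height", "escalator_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BuildingParams.{name} must be positive")


@dataclass
class Environment:
    """A fully realised two-floor building: geometry plus semantic elements."""

    atria_type: str
    params: BuildingParams
    floors: list[FloorPlan]
    occluders: list[RectOccluder]
    atria: list[Polygon]
    destinations: list[Destination]
    escalator: Escalator | None
    entrance: Pose

    def destination(self, dest_id: str) -> Destination:
        for d in self.destinations:
            if d.id == dest_id:
                return d
        raise KeyError(f"unknown destination {dest_id!r}")

    def floor_at_z(self, z: float) -> int:
        """Index of the floor whose [elevation, elevation+ceiling) band holds z."""
        for i, fl in enumerate(self.floors):
            if fl.elevation <= z < fl.elevation + fl.ceiling_height + 1e-9:
                return i
        raise ValueError(f"z={z} is outside every floor band")

    @property
    def atria_area(self) -> float:
        return float(sum(a.area for a in self.atria))


class ConfigurationError(ValueError):
    pass


def _atria_polygons(atria_type: str, params: BuildingParams) -> list[Polygon]:
    # Void rectangles are constructed to sum exactly to the configured area.
    if atria_type == "centralized":
        polys = [box(7.0, -6.0, 31.0, 6.0)]  # 24 x 12 = 288
    else:
        polys = [
            box(6.0, -6.0, 14.0, 6.0),  # 8 x 12 = 96
            box(15.0, -6.0, 23.0, 6.0),
            box(24.0, -6.0, 32.0, 6.0),
        ]
    total = sum(p.area for p in polys)
    if abs(total - params.atria_total_area) > 1e-6 * params.atria_total_area:
        raise ConfigurationError(
            f"atria layout area {total} m^2 inconsistent with configured total "
            f"{params.atria_total_area} m^2"
        )
    return polys


def build_building(atria_type: str, params: BuildingParams | None = None) -> Environment:
    """Construct one of the two study buildings.

    The two atria types share byte-identical first floors and differ only in
    the second-floor void layout; the fence confining second-floor movement to
    the perimeter walkway is identical in both.
    """
    if atria_type not in ATRIA_TYPES:
        raise ConfigurationError(
            f"atria_type must be one of {ATRIA_TYPES}, got {atria_type!r}"
        )
    params = params or BuildingParams()
    params.validate()

    L, W = params.length, params.width
    hw = W / 2.0
    rd = params.room_depth
    fh = params.floor_height
    roof_z = fh + params.ceiling_height
    open_hw = hw - rd  # half-width of the first-floor open hall
    hall_len = L - rd  # hall runs from the entrance wall to the far room ring

    footprint = box(0.0, -hw, L, hw)

    # --- first floor -----------------------------------------------------
    ex0, ey0 = params.escalator_base
    ex1, ey1 = params.escalator_top
    ew = params.escalator_width / 2.0
    # The ramp footprint plus the strip to the side wall is fenced off at
    # ground level so the hall polygon stays simple (no interior hole).
    notch = box(min(ex0, ex1), -open_hw, max(ex0, ex1), ey0 + ew)
    hall = box(0.0, -open_hw, hall_len, open_hw).difference(notch)
    rooms1 = [
        box(0.0, open_hw, L, hw),       # left (y > 0) room strip
        box(0.0, -hw, L, -open_hw),     # right room strip
        box(hall_len, -open_hw, L, open_hw),  # far room strip
    ]
    floor1 = FloorPlan(footprint=footprint, elevation=0.0,
                       ceiling_height=fh, walkable=hall, rooms=rooms1)

    # --- second floor ----------------------------------------------------
    fence_rect = box(params.fence_x[0], params.fence_y[0],
                     params.fence_x[1], params.fence_y[1])
    rooms2 = [
        box(0.0, hw - 2.0, 2.0, hw),        # backwards-facing, left
        box(0.0, -hw, 2.0, -(hw - 2.0)),    # backwards-facing, right
        box(L - 2.0, hw - 2.0, L, hw),      # forward-facing, left
        box(L - 2.0, -hw, L, -(hw - 2.0)),  # forward-facing, right
    ]
    walk2 = footprint.difference(fence_rect)
    for r in rooms2:
        walk2 = walk2.difference(r)
    floor2 = FloorPlan(footprint=footprint, elevation=fh,
                       ceiling_height=params.ceiling_height,
                       walkable=walk2, rooms=rooms2)

    atria = _atria_polygons(atria_type, params)

    # --- destinations -----------------------------------------------------
    dw, dh = params.door_width, params.door_height
    dz0, dz1 = fh, fh + dh
    d2 = [
        Destination("F2-forward-left", 1, "x", L - 2.0, hw - 1.5 - dw / 2, hw - 1.5 + dw / 2,
                    dz0, dz1, -1, "entrance-forward-facing", "left"),
        Destination("F2-forward-right", 1, "x", L - 2.0, -(hw - 1.5) - dw / 2, -(hw - 1.5) + dw / 2,
                    dz0, dz1, -1, "entrance-forward-facing", "right"),
        Destination("F2-backward-left", 1, "x", 2.0, hw - 1.0 - dw / 2, hw - 1.0 + dw / 2,
                    dz0, dz1, +1, "entrance-backwards-facing", "left"),
        Destination("F2-backward-right", 1, "x", 2.0, -(hw - 1.0) - dw / 2, -(hw - 1.0) + dw / 2,
                    dz0, dz1, +1, "entrance-backwards-facing", "right"),
    ]
    d1 = [
        Destination("F1-forward-left", 0, "x", hall_len, 3.0 - dw / 2, 3.0 + dw / 2,
                    0.0, dh, -1, "entrance-forward-facing", "left"),
        Destination("F1-forward-right", 0, "x", hall_len, -3.0 - dw / 2, -3.0 + dw / 2,
                    0.0, dh, -1, "entrance-forward-facing", "right"),
        Destination("F1-backward-left", 0, "y", open_hw, 2.0 - dw / 2, 2.0 + dw / 2,
                    0.0, dh, -1, "entrance-backwards-facing", "left"),
        Destination("F1-backward-right", 0, "y", -open_hw, 2.0 - dw / 2, 2.0 + dw / 2,
                    0.0, dh, +1, "entrance-backwards-facing", "right"),
    ]
    destinations = d1 + d2

    # --- occluders ---------------------------------------------------------
    def door_hole(d: Destination) -> tuple[float, float, float, float]:
        return (d.umin, d.umax, d.zmin, d.zmax)

    occ: list[RectOccluder] = [
        # exterior shell, both storeys
        RectOccluder("x", 0.0, -hw, hw, 0.0, roof_z, kind="wall"),
        RectOccluder("x", L, -hw, hw, 0.0, roof_z, kind="wall"),
        RectOccluder("y", hw, 0.0, L, 0.0, roof_z, kind="wall"),
        RectOccluder("y", -hw, 0.0, L, 0.0, roof_z, kind="wall"),
        # first-floor room ring walls facing the hall (glass doors are holes)
        RectOccluder("y", open_hw, 0.0, L, 0.0, fh,
                     holes=(door_hole(d1[2]),), kind="wall"),
        RectOccluder("y", -open_hw, 0.0, L, 0.0, fh,
                     holes=(door_hole(d1[3]),), kind="wall"),
        RectOccluder("x", hall_len, -open_hw, open_hw, 0.0, fh,
                     holes=(door_hole(d1[0]), door_hole(d1[1])), kind="wall"),
    ]
    # second-floor slab with atria voids and the escalator cutout
    esc_len = abs(ex0 - ex1)
    cut_x0 = min(ex0, ex1) + 0.1
    # cutout reaches to where headroom over the ramp clears the slab
    cut_x1 = max(ex0, ex1) - esc_len * max(0.0, (fh - 1.8)) / fh
    slab_holes = tuple((p.bounds[0], p.bounds[2], p.bounds[1], p.bounds[3]) for p in atria)
    slab_holes += ((cut_x0, cut_x1, ey0 - ew, ey0 + ew),)
    occ.append(RectOccluder("z", fh, 0.0, L, -hw, hw, holes=slab_holes, kind="slab"))
    occ.append(RectOccluder("z", roof_z, 0.0, L, -hw, hw, kind="roof"))
    occ.append(RectOccluder("z", 0.0, 0.0, L, -hw, hw, kind="floor"))
    # fence around the second-floor void region (1 m parapet)
    fx0, fx1 = params.fence_x
    fy0, fy1 = params.fence_y
    fz0, fz1 = fh, fh + params.fence_height
    occ += [
        RectOccluder("x", fx0, fy0, fy1, fz0, fz1, kind="fence"),
        RectOccluder("x", fx1, fy0, fy1, fz0, fz1, kind="fence"),
        RectOccluder("y", fy0, fx0, fx1, fz0, fz1, kind="fence"),
        RectOccluder("y", fy1, fx0, fx1, fz0, fz1, kind="fence"),
    ]
    # second-floor corner room walls (inner faces only; doors are glass holes)
    occ += [
        RectOccluder("x", 2.0, hw - 2.0, hw, fh, roof_z,
                     holes=(door_hole(d2[2]),), kind="wall"),
        RectOccluder("y", hw - 2.0, 0.0, 2.0, fh, roof_z, kind="wall"),
        RectOccluder("x", 2.0, -hw, -(hw - 2.0), fh, roof_z,
                     holes=(door_hole(d2[3]),), kind="wall"),
        RectOccluder("y", -(hw - 2.0), 0.0, 2.0, fh, roof_z, kind="wall"),
        RectOccluder("x", L - 2.0, hw - 2.0, hw, fh, roof_z,
                     holes=(door_hole(d2[0]),), kind="wall"),
        RectOccluder("y", hw - 2.0, L - 2.0, L, fh, roof_z, kind="wall"),
        RectOccluder("x", L - 2.0, -hw, -(hw - 2.0), fh, roof_z,
                     holes=(door_hole(d2[1]),), kind="wall"),
        RectOccluder("y", -(hw - 2.0), L - 2.0, L, fh, roof_z, kind="wall"),
    ]

    escalator = Escalator(base=(ex0, ey0, 0.0), top=(ex1, ey1, fh))
    entrance = Pose(params.entrance_x, 0.0, 0.0, yaw=0.0, pitch=0.0)

    env = Environment(
        atria_type=atria_type,
        params=params,
        floors=[floor1, floor2],
        occluders=occ,
        atria=atria,
        destinations=destinations,
        escalator=escalator,
        entrance=entrance,
    )
    _check_invariants(env)
    return env


def _check_invariants(env: Environment) -> None:
    p = env.params
    if abs(env.atria_area - p.atria_total_area) > 1e-6 * p.atria_total_area:
        raise ConfigurationError("atria void area deviates from the configured total")
    n_by_floor = [0, 0]
    for d in env.destinations:
        n_by_floor[d.floor] += 1
    if n_by_floor != [4, 4] or len(env.destinations) != 8:
        raise ConfigurationError("environment must hold 8 destinations, 4 per floor")
    for fl in (0, 1):
        fwd = sum(1 for d in env.destinations
                  if d.floor == fl and d.facing == "entrance-forward-facing")
        if fwd != 2:
            raise ConfigurationError("each floor needs 2 forward- and 2 backwards-facing doors")


# ---------------------------------------------------------------------------
# Convex zone decomposition
# ---------------------------------------------------------------------------

@dataclass
class Zone:
    id: str
    floor: int
    polygon: Polygon
    adjacent: set[str] = field(default_factory=set)


class GeometryError(ValueError):
    pass


def _is_convex(poly: Polygon, tol: float = 1e-9) -> bool:
    hull = poly.convex_hull
    return abs(hull.area - poly.area) <= tol * max(hull.area, 1.0)


def _reflex_cut(poly: Polygon) -> LineString | None:
    """A splitting line through the first reflex vertex found, or None."""
    ext = poly.exterior
    coords = list(ext.coords)[:-1]
    n = len(coords)
    ccw = ext.is_ccw
    span = 4.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    for i in range(n):
        p0 = np.array(coords[(i - 1) % n])
        p1 = np.array(coords[i])
        p2 = np.array(coords[(i + 1) % n])
        a, b = p1 - p0, p2 - p1
        cross = a[0] * b[1] - a[1] * b[0]
        if (cross < -1e-9 and ccw) or (cross > 1e-9 and not ccw):
            # reflex: extend the incoming edge through the vertex
            for d in (a, b):
                nd = np.linalg.norm(d)
                if nd < 1e-12:
                    continue
                u = d / nd
                return LineString([p1 - u * span, p1 + u * span])
    return None


def _split_convex(poly: Polygon, depth: int = 0) -> list[Polygon]:
    if depth > 60:
        raise GeometryError("convex decomposition did not terminate")
    if poly.is_empty or poly.area < 1e-12:
        return []
    if not poly.is_valid:
        poly = poly.buffer(0)
    # polygons with holes: cut through the first hole's centroid
    if poly.interiors:
        cx = poly.interiors[0].centroid.x
        y0, y1 = poly.bounds[1] - 1.0, poly.bounds[3] + 1.0
        pieces = shapely_split(poly, LineString([(cx, y0), (cx, y1)]))
        out: list[Polygon] = []
        for g in pieces.geoms:
            if isinstance(g, Polygon):
                out.extend(_split_convex(g, depth + 1))
        return out
    if _is_convex(poly, tol=1e-9):
        return [poly]
    cut = _reflex_cut(poly)
    if cut is None:  # numerically convex
        return [poly]
    pieces = shapely_split(poly, cut)
    polys = [g for g in pieces.geoms if isinstance(g, Polygon) and g.area > 1e-10]
    if len(polys) <= 1:
        # cut failed to bisect; fall back to an axis-aligned halving
        x0, y0, x1, y1 = poly.bounds
        if x1 - x0 >= y1 - y0:
            cut = LineString([((x0 + x1) / 2, y0 - 1), ((x0 + x1) / 2, y1 + 1)])
        else:
            cut = LineString([(x0 - 1, (y0 + y1) / 2), (x1 + 1, (y0 + y1) / 2)])
        pieces = shapely_split(poly, cut)
        polys = [g for g in pieces.geoms if isinstance(g, Polygon) and g.area > 1e-10]
    out = []
    for g in polys:
        out.extend(_split_convex(g, depth + 1))
    return out


def decompose_walkable(poly: Polygon, max_span: float | None = None) -> list[Polygon]:
    """Split a walkable polygon into convex pieces.

    With ``max_span`` set, convex pieces wider than the span are further
    halved (straight cuts preserve convexity) to yield finer zones.
    """
    if poly.is_empty:
        raise GeometryError("empty walkable polygon")
    if not poly.is_valid:
        raise GeometryError("non-simple walkable polygon")
    parts = _split_convex(poly)
    if max_span is not None:
        queue = list(parts)
        parts = []
        while queue:
            g = queue.pop()
            x0, y0, x1, y1 = g.bounds
            if max(x1 - x0, y1 - y0) <= max_span:
                parts.append(g)
                continue
            if x1 - x0 >= y1 - y0:
                cut = LineString([((x0 + x1) / 2, y0 - 1), ((x0 + x1) / 2, y1 + 1)])
            else:
                cut = LineString([(x0 - 1, (y0 + y1) / 2), (x1 + 1, (y0 + y1) / 2)])
            queue.extend(g2 for g2 in shapely_split(g, cut).geoms
                         if isinstance(g2, Polygon) and g2.area > 1e-10)
    return parts


def decompose_zones(env: Environment, max_span: float | None = None) -> list[Zone]:
    """Tile each floor's walkable area with convex zones and link neighbours."""
    zones: list[Zone] = []
    for fi, fl in enumerate(env.floors):
        parts = decompose_walkable(fl.walkable, max_span=max_span)
        total = sum(p.area for p in parts)
        if abs(total - fl.walkable.area) > 1e-6 * max(fl.walkable.area, 1.0):
            raise GeometryError("zone tiling lost area on floor %d" % fi)
        for k, p in enumerate(parts):
            zones.append(Zone(id=f"z{fi}-{k}", floor=fi, polygon=p))
    # adjacency: shared boundary of positive length, same floor
    for i, zi in enumerate(zones):
        for zj in zones[i + 1:]:
            if zi.floor != zj.floor:
                continue
            inter = zi.polygon.intersection(zj.polygon)
            if inter.length > 1e-9:
                zi.adjacent.add(zj.id)
                zj.adjacent.add(zi.id)
    return zones


# ---------------------------------------------------------------------------
# Navigation grid
# ---------------------------------------------------------------------------

@dataclass
class FloorGrid:
    origin: tuple[float, float]
    nx: int
    ny: int
    walkable: np.ndarray  # bool (nx, ny)
    elevation: float


@dataclass
class NavGrid:
    """Per-floor square-cell walkability rasters plus the escalator link.

    Cells are addressed ``(floor, i, j)``; centres sit at half-cell offsets
    from each floor's origin.
    """

    resolution: float
    floors: list[FloorGrid]
    link: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None
    link_length: float = 0.0
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def cell_center(self, cell: tuple[int, int, int]) -> np.ndarray:
        f, i, j = cell
        fg = self.floors[f]
        return np.array([
            fg.origin[0] + (i + 0.5) * self.resolution,
            fg.origin[1] + (j + 0.5) * self.resolution,
        ])

    def cell_elevation(self, cell: tuple[int, int, int]) -> float:
        return self.floors[cell[0]].elevation

    def walkable_cells(self, floor: int) -> list[tuple[int, int, int]]:
        fg = self.floors[floor]
        return [(floor, int(i), int(j)) for i, j in zip(*np.nonzero(fg.walkable))]

    def cell_centers(self, floor: int) -> np.ndarray:
        """(N, 2) centres of walkable cells on one floor, in index order."""
        fg = self.floors[floor]
        ii, jj = np.nonzero(fg.walkable)
        return np.column_stack([
            fg.origin[0] + (ii + 0.5) * self.resolution,
            fg.origin[1] + (jj + 0.5) * self.resolution,
        ])

    def nearest_cell(self, floor: int, xy: Sequence[float]) -> tuple[int, int, int]:
        fg = self.floors[floor]
        centers = self.cell_centers(floor)
        if len(centers) == 0:
            raise GeometryError("floor has no walkable cells")
        d2 = np.sum((centers - np.asarray(xy[:2])) ** 2, axis=1)
        k = int(np.argmin(d2))
        ii, jj = np.nonzero(fg.walkable)
        return (floor, int(ii[k]), int(jj[k]))

    def is_walkable(self, cell: tuple[int, int, int]) -> bool:
        f, i, j = cell
        fg = self.floors[f]
        return 0 <= i < fg.nx and 0 <= j < fg.ny and bool(fg.walkable[i, j])

    def graph(self) -> nx.Graph:
        """8-connected lattice graph (no corner cutting) with the escalator edge."""
        if self._graph is not None:
            return self._graph
        g = nx.Graph()
        res = self.resolution
        diag = math.sqrt(2.0) * res
        for f, fg in enumerate(self.floors):
            walk = fg.walkable
            ii, jj = np.nonzero(walk)
            for i, j in zip(ii, jj):
                g.add_node((f, int(i), int(j)))
            for i, j in zip(ii, jj):
                for di, dj in ((1, 0), (0, 1), (1, 1), (1, -1)):
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < fg.nx and 0 <= nj < fg.ny and walk[ni, nj]):
                        continue
                    if di != 0 and dj != 0:
                        # both orthogonal neighbours must be free (no corner cut)
                        if not (walk[i + di, j] and walk[i, j + dj]):
                            continue
                        g.add_edge((f, int(i), int(j)), (f, int(ni), int(nj)), weight=diag)
                    else:
                        g.add_edge((f, int(i), int(j)), (f, int(ni), int(nj)), weight=res)
        if self.link is not None:
            g.add_edge(self.link[0], self.link[1], weight=self.link_length)
        self._graph = g
        return g


def build_nav_grid(env: Environment, resolution: float,
                   clearance: float = 0.2) -> NavGrid:
    """Rasterise each floor's walkable polygon into square cells.

    A cell is walkable when its centre lies inside the walkable polygon eroded
    by ``clearance`` (half a shoulder width of slack from walls).  A warning
    flag is raised through ``GeometryError`` only for non-positive resolution;
    a too-coarse grid simply yields fewer (possibly disconnected) cells.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    floors = []
    for fl in env.floors:
        x0, y0, x1, y1 = fl.footprint.bounds
        nx_ = max(1, int(math.ceil((x1 - x0) / resolution - 1e-9)))
        ny_ = max(1, int(math.ceil((y1 - y0) / resolution - 1e-9)))
        xs = x0 + (np.arange(nx_) + 0.5) * resolution
        ys = y0 + (np.arange(ny_) + 0.5) * resolution
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        region = fl.walkable.buffer(-clearance) if clearance > 0 else fl.walkable
        mask = contains_xy(region, xx.ravel(), yy.ravel()).reshape(nx_, ny_)
        floors.append(FloorGrid(origin=(x0, y0), nx=nx_, ny=ny_,
                                walkable=mask, elevation=fl.elevation))
    grid = NavGrid(resolution=resolution, floors=floors)
    if env.escalator is not None and len(floors) > 1:
        base = grid.nearest_cell(0, env.escalator.base)
        top = grid.nearest_cell(1, env.escalator.top)
        grid.link = (base, top)
        grid.link_length = env.escalator.length
    return grid
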