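"""Wayfinding agents: the visibility-based cognitive agent and an A* baseline.

The cognitive agent is a finite-state machine driven entirely by what it can
currently see.  From the spawn state it checks whether the destination door
falls inside its three-dimensional field of view: if so it heads for the
escalator (Move to Escalator and Switch Floor), otherwise it explores.
Exploration steers towards the visible navigation cell with the minimal
pre-computed isovist drift whose convex zone has not been traversed yet (a
short-term memory that prevents looping).  Once no unvisited zone remains in
reach the first floor counts as sufficiently explored and the agent heads for
the escalator regardless.  After switching floors the agent either plans a
shortest path to the destination (if visible) or keeps following minimal
drift cells on the second floor.

The baseline agent ignores visibility altogether and walks the A* shortest
path from the entrance to the destination, which necessarily passes the
escalator.  Both agents share kinematics: 1.3 m/s forward speed, 0.6 m/s
lateral/backward, 1.8 m tall with 1.7 m eye height, turning at a finite rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np

from .building import Destination, Environment, NavGrid, Pose, Zone, normalize_yaw
from .trajectory import Trajectory
from .visibility import DriftField, FieldOfView, destination_visibility, occluder_segments_2d

AGENT_FOV = FieldOfView(horizontal_angle=150.0, vertical_angle=60.0, view_range=100.0)

MODES = ("INITIAL", "EXPLORE", "MOVE_TO_ESCALATOR", "RIDE_ESCALATOR",
         "MOVE_TO_DESTINATION", "DONE", "FAILED")


@dataclass
class AgentParams:
    height: float = 1.8
    eye_height: float = 1.7
    shoulder_width: float = 0.25
    forward_speed: float = 1.3
    lateral_backward_speed: float = 0.6
    fov: FieldOfView = AGENT_FOV
    turn_rate: float = 90.0  # deg/s
    dt: float = 0.1
    log_every: float = 0.2
    arrival_tol: float = 0.5
    waypoint_tol: float = 0.3
    align_tol: float = 45.0  # move only when heading within this of the waypoint
    max_time: float = 300.0
    n_sight_rays: int = 9

    def __post_init__(self) -> None:
        if min(self.forward_speed, self.lateral_backward_speed, self.dt,
               self.turn_rate) <= 0:
            raise ValueError("speeds, dt and turn_rate must be positive")


@dataclass
class Percept:
    destination_in_sight: bool
    visible_cells: np.ndarray  # indices into the floor's walkable-cell list
    visible_drift: np.ndarray


@dataclass
class AgentState:
    pose: Pose
    floor: int
    mode: str = "INITIAL"
    visited_zones: set[str] = dc_field(default_factory=set)
    plan: list[np.ndarray] = dc_field(default_factory=list)
    target_zone: str | None = None
    ride_progress: float = 0.0
    time: float = 0.0
    failed: bool = False
    explore_targets: list[str] = dc_field(default_factory=list)
    _dead_zones: set[str] = dc_field(default_factory=set)


class AgentWorld:
    """Pre-computed perception tables for one (environment, grid, zones, field)."""

    def __init__(self, env: Environment, grid: NavGrid, zones: list[Zone],
                 field: DriftField, params: AgentParams | None = None):
        from shapely import contains_xy

        self.env = env
        self.grid = grid
        self.zones = zones
        self.field = field
        self.params = params or AgentParams()
        self.zone_by_id = {z.id: z for z in zones}
        self.segments: list[np.ndarray] = []
        self.centers: list[np.ndarray] = []
        self.cells: list[list[tuple[int, int, int]]] = []
        self.drift: list[np.ndarray] = []
        self.cell_zone: list[np.ndarray] = []
        for f, fl in enumerate(env.floors):
            z_eye = fl.elevation + self.params.eye_height
            self.segments.append(occluder_segments_2d(env, z_eye))
            centers = grid.cell_centers(f)
            self.centers.append(centers)
            self.cells.append(grid.walkable_cells(f))
            self.drift.append(field.floor_values(f))
            zone_idx = np.full(len(centers), -1, dtype=int)
            floor_zones = [z for z in zones if z.floor == f]
            for z in floor_zones:
                m = contains_xy(z.polygon.buffer(1e-9), centers[:, 0], centers[:, 1])
                zone_idx[m & (zone_idx == -1)] = zones.index(z)
            self.cell_zone.append(zone_idx)

    # -- geometry helpers -------------------------------------------------
    def eye(self, state: AgentState) -> np.ndarray:
        fl = self.env.floors[state.floor]
        z = fl.elevation + self.params.eye_height
        if state.mode == "RIDE_ESCALATOR" and self.env.escalator is not None:
            esc = self.env.escalator
            frac = state.ride_progress / max(esc.length, 1e-9)
            z = esc.base[2] + frac * (esc.top[2] - esc.base[2]) + self.params.eye_height
        return np.array([state.pose.x, state.pose.y, z])

    def zone_of(self, floor: int, xy: np.ndarray) -> str | None:
        fg = self.grid.floors[floor]
        i = int((xy[0] - fg.origin[0]) // self.grid.resolution)
        j = int((xy[1] - fg.origin[1]) // self.grid.resolution)
        if not (0 <= i < fg.nx and 0 <= j < fg.ny) or not fg.walkable[i, j]:
            # off the lattice (e.g. skimming a wall): fall back to nearest cell
            cell = self.grid.nearest_cell(floor, xy)
            i, j = cell[1], cell[2]
        try:
            k = self.cells[floor].index((floor, i, j))
        except ValueError:
            return None
        zi = self.cell_zone[floor][k]
        return self.zones[zi].id if zi >= 0 else None

    def los_clear(self, floor: int, origin: np.ndarray, targets: np.ndarray) -> np.ndarray:
        """2D line-of-sight from origin to each target on one floor."""
        segs = self.segments[floor]
        n = len(targets)
        if len(segs) == 0:
            return np.ones(n, dtype=bool)
        d = targets - origin[None, :]
        p0 = segs[:, 0:2]
        e = segs[:, 2:4] - p0
        w = p0 - origin[None, :]
        denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]) / denom
            s = (w[None, :, 0] * d[:, None, 1] - w[None, :, 1] * d[:, None, 0]) / denom
        hit = (np.abs(denom) > 1e-14) & (t > 1e-9) & (t < 1 - 1e-9) \
            & (s >= -1e-12) & (s <= 1 + 1e-12)
        return ~hit.any(axis=1)


def perceive(state: AgentState, world: AgentWorld, dest: Destination) -> Percept:
    """What the agent currently sees: the destination flag and drift cells."""
    p = world.params
    eye = world.eye(state)
    pose = Pose(eye[0], eye[1], eye[2], yaw=state.pose.yaw, pitch=state.pose.pitch)
    sample = destination_visibility(pose, dest, world.env, fov=p.fov,
                                    n_rays=p.n_sight_rays)
    in_sight = sample.n_rays_reaching > 0
    centers = world.centers[state.floor]
    d = centers - eye[None, :2]
    dist = np.hypot(d[:, 0], d[:, 1])
    az = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    d_az = np.abs((az - pose.yaw + 180.0) % 360.0 - 180.0)
    cone = (dist <= p.fov.view_range) & (d_az <= p.fov.horizontal_angle / 2.0) \
        & (dist > 1e-9)
    idx = np.nonzero(cone)[0]
    if len(idx):
        clear = world.los_clear(state.floor, eye[:2], centers[idx])
        idx = idx[clear]
    return Percept(destination_in_sight=in_sight, visible_cells=idx,
                   visible_drift=world.drift[state.floor][idx] if len(idx) else np.empty(0))


def plan_shortest_path(grid: NavGrid, start: tuple[int, int, int],
                       goal: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """A* cell path under the 8-connected grid metric (Euclidean heuristic)."""
    if not grid.is_walkable(start) or not grid.is_walkable(goal):
        raise ValueError("start and goal must be walkable cells")
    g = grid.graph()

    def h(a, b):
        ca, cb = grid.cell_center(a), grid.cell_center(b)
        dz = grid.cell_elevation(a) - grid.cell_elevation(b)
        return math.sqrt(float(np.sum((ca - cb) ** 2)) + dz * dz)

    return nx.astar_path(g, start, goal, heuristic=h, weight="weight")


def _path_waypoints(world: AgentWorld, floor: int, xy: np.ndarray,
                    goal_cell: tuple[int, int, int],
                    final_point: np.ndarray | None = None) -> list[np.ndarray]:
    start = world.grid.nearest_cell(floor, xy)
    cells = plan_shortest_path(world.grid, start, goal_cell)
    wps = [world.grid.cell_center(c) for c in cells if c[0] == floor]
    if final_point is not None:
        wps.append(np.asarray(final_point[:2], dtype=float))
    return wps


def _advance(state: AgentState, waypoint: np.ndarray, speed: float,
             p: AgentParams) -> bool:
    """Turn towards the waypoint and move; True when the waypoint is reached."""
    dx = waypoint[0] - state.pose.x
    dy = waypoint[1] - state.pose.y
    dist = math.hypot(dx, dy)
    if dist < p.waypoint_tol:
        return True
    desired = math.degrees(math.atan2(dy, dx))
    dyaw = normalize_yaw(desired - state.pose.yaw)
    max_turn = p.turn_rate * p.dt
    state.pose.yaw = normalize_yaw(state.pose.yaw + float(np.clip(dyaw, -max_turn, max_turn)))
    if abs(normalize_yaw(desired - state.pose.yaw)) <= p.align_tol:
        step = min(speed * p.dt, dist)
        state.pose.x += step * dx / dist
        state.pose.y += step * dy / dist
    return math.hypot(waypoint[0] - state.pose.x, waypoint[1] - state.pose.y) < p.waypoint_tol


def _ride_step(state: AgentState, esc, p: AgentParams) -> bool:
    """One dt of escalator riding; True once the top is reached.

    Entering with ``ride_progress < 0`` means "walk to the base first": the
    agent closes the gap at walking speed so no logged step exceeds the
    speed cap.
    """
    if state.ride_progress < 0:
        dx = esc.base_xy[0] - state.pose.x
        dy = esc.base_xy[1] - state.pose.y
        dist = math.hypot(dx, dy)
        step = p.forward_speed * p.dt
        if dist > step:
            state.pose.x += step * dx / dist
            state.pose.y += step * dy / dist
            return False
        state.pose.x, state.pose.y = float(esc.base_xy[0]), float(esc.base_xy[1])
        state.ride_progress = 0.0
        return False
    state.ride_progress = min(state.ride_progress + p.forward_speed * p.dt,
                              esc.length)
    frac = state.ride_progress / esc.length
    xy = esc.base_xy + frac * (esc.top_xy - esc.base_xy)
    state.pose.x, state.pose.y = float(xy[0]), float(xy[1])
    d = esc.top_xy - esc.base_xy
    if np.hypot(*d) > 1e-9:
        state.pose.yaw = normalize_yaw(math.degrees(math.atan2(d[1], d[0])))
    return state.ride_progress >= esc.length - 1e-9


def _choose_explore_target(state: AgentState, percept: Percept,
                           world: AgentWorld) -> tuple[int, int, int] | None:
    """Minimal-drift cell in an unvisited zone; visible cells take priority."""
    floor = state.floor
    zone_idx = world.cell_zone[floor]
    blocked = state.visited_zones | state._dead_zones

    def pick(cand_idx: np.ndarray) -> tuple[int, int, int] | None:
        if len(cand_idx) == 0:
            return None
        drift = world.drift[floor][cand_idx]
        centers = world.centers[floor][cand_idx]
        here = np.array([state.pose.x, state.pose.y])
        dist = np.hypot(centers[:, 0] - here[0], centers[:, 1] - here[1])
        order = np.lexsort((cand_idx, dist, np.round(drift, 9)))
        return world.cells[floor][int(cand_idx[order[0]])]

    def admissible(idx: np.ndarray) -> np.ndarray:
        zi = zone_idx[idx]
        ok = zi >= 0
        names = np.array([world.zones[k].id if k >= 0 else "" for k in zi])
        for b in blocked:
            ok &= names != b
        return idx[ok]

    target = pick(admissible(percept.visible_cells))
    if target is not None:
        return target
    return pick(admissible(np.arange(len(world.cells[floor]))))


def agent_step(state: AgentState, percept: Percept, world: AgentWorld,
               dest: Destination) -> AgentState:
    """One dt of the cognitive agent's FSM: transition, then move."""
    p = world.params
    env = world.env
    here = np.array([state.pose.x, state.pose.y])
    z = world.zone_of(state.floor, here)
    if z is not None:
        state.visited_zones.add(z)

    if state.mode == "INITIAL":
        if percept.destination_in_sight:
            state.mode = "MOVE_TO_ESCALATOR"
            base = world.grid.link[0]
            state.plan = _path_waypoints(world, 0, here, base,
                                         final_point=env.escalator.base_xy)
        else:
            state.mode = "EXPLORE"
            state.plan = []

    if state.mode == "EXPLORE":
        if percept.destination_in_sight:
            if state.floor == 0:
                state.mode = "MOVE_TO_ESCALATOR"
                base = world.grid.link[0]
                state.plan = _path_waypoints(world, 0, here, base,
                                             final_point=env.escalator.base_xy)
            else:
                state.mode = "MOVE_TO_DESTINATION"
                goal = world.grid.nearest_cell(1, dest.approach_point())
                state.plan = _path_waypoints(world, 1, here, goal,
                                             final_point=dest.approach_point())
        elif not state.plan:
            target = _choose_explore_target(state, percept, world)
            if target is None:
                if state.floor == 0:
                    state.mode = "MOVE_TO_ESCALATOR"
                    base = world.grid.link[0]
                    state.plan = _path_waypoints(world, 0, here, base,
                                                 final_point=env.escalator.base_xy)
                else:
                    state.failed = True
                    state.mode = "FAILED"
                    return state
            else:
                tz = world.zones[world.cell_zone[state.floor][
                    world.cells[state.floor].index(target)]].id
                state.target_zone = tz
                state.explore_targets.append(tz)
                try:
                    state.plan = _path_waypoints(world, state.floor, here, target)
                except nx.NetworkXNoPath:
                    state._dead_zones.add(tz)
                    return state

    if state.mode in ("EXPLORE", "MOVE_TO_ESCALATOR", "MOVE_TO_DESTINATION") and state.plan:
        reached = _advance(state, state.plan[0], p.forward_speed, p)
        if reached:
            state.plan.pop(0)
        if not state.plan:
            if state.mode == "MOVE_TO_ESCALATOR":
                state.mode = "RIDE_ESCALATOR"
                state.ride_progress = -1.0
            elif state.mode == "MOVE_TO_DESTINATION":
                state.mode = "DONE"
            elif state.target_zone is not None:
                # explore target reached: its zone now counts as traversed
                state.visited_zones.add(state.target_zone)
                state.target_zone = None
    elif state.mode == "RIDE_ESCALATOR":
        if _ride_step(state, env.escalator, p):
            state.floor = 1
            state.mode = "EXPLORE"
            state.plan = []
            post = perceive(state, world, dest)
            if post.destination_in_sight:
                state.mode = "MOVE_TO_DESTINATION"
                goal = world.grid.nearest_cell(1, dest.approach_point())
                state.plan = _path_waypoints(world, 1,
                                             np.array([state.pose.x, state.pose.y]),
                                             goal, final_point=dest.approach_point())
    state.time += p.dt
    return state


def run_trial(agent_type: str, env: Environment, grid: NavGrid,
              field: DriftField, dest: Destination | str,
              initial_heading: float, seed: int = 0,
              zones: list[Zone] | None = None,
              world: AgentWorld | None = None,
              params: AgentParams | None = None,
              agent_id: str = "agent-0") -> Trajectory:
    """Simulate one trial from the entrance; poses are logged every 0.2 s.

    ``agent_type`` is ``"cognitive"`` or ``"shortest_path"``.  The trial is
    deterministic given (environment, destination, initial heading); ``seed``
    is accepted for interface symmetry and reserved for stochastic variants.
    Incomplete trials carry ``meta['complete'] = False``.
    """
    from .building import decompose_zones

    if agent_type not in ("cognitive", "shortest_path"):
        raise ValueError("agent_type must be 'cognitive' or 'shortest_path'")
    if isinstance(dest, str):
        dest = env.destination(dest)
    if world is None:
        if zones is None:
            zones = decompose_zones(env)
        world = AgentWorld(env, grid, zones, field, params=params)
    p = world.params
    state = AgentState(
        pose=Pose(env.entrance.x, env.entrance.y, env.entrance.z,
                  yaw=initial_heading, pitch=0.0),
        floor=0,
    )
    log_stride = max(1, int(round(p.log_every / p.dt)))
    rows = []

    def log() -> None:
        eye = world.eye(state)
        rows.append((state.time, state.pose.x, state.pose.y, eye[2],
                     state.pose.yaw, state.pose.pitch))

    log()
    n_steps = int(p.max_time / p.dt)
    if agent_type == "shortest_path":
        base = world.grid.link[0]
        plan1 = _path_waypoints(world, 0, np.array([state.pose.x, state.pose.y]),
                                base, final_point=env.escalator.base_xy)
        goal = world.grid.nearest_cell(1, dest.approach_point())
        plan2 = _path_waypoints(world, 1, env.escalator.top_xy, goal,
                                final_point=dest.approach_point())
        state.mode = "MOVE_TO_ESCALATOR"
        state.plan = plan1
        for k in range(1, n_steps + 1):
            if state.mode == "MOVE_TO_ESCALATOR":
                if state.plan and _advance(state, state.plan[0], p.forward_speed, p):
                    state.plan.pop(0)
                if not state.plan:
                    state.mode = "RIDE_ESCALATOR"
                    state.ride_progress = -1.0
            elif state.mode == "RIDE_ESCALATOR":
                if _ride_step(state, env.escalator, p):
                    state.floor = 1
                    state.mode = "MOVE_TO_DESTINATION"
                    state.plan = plan2
            elif state.mode == "MOVE_TO_DESTINATION":
                if state.plan and _advance(state, state.plan[0], p.forward_speed, p):
                    state.plan.pop(0)
                if not state.plan:
                    state.mode = "DONE"
            state.time += p.dt
            if k % log_stride == 0:
                log()
            if state.mode == "DONE":
                break
    else:
        for k in range(1, n_steps + 1):
            if state.mode in ("DONE", "FAILED"):
                break
            percept = perceive(state, world, dest)
            state = agent_step(state, percept, world, dest)
            if k % log_stride == 0:
                log()
    if rows[-1][0] < state.time:
        log()
    arr = np.array(rows)
    source = "cognitive_agent" if agent_type == "cognitive" else "shortest_path_agent"
    return Trajectory(
        t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], z=arr[:, 3],
        yaw=arr[:, 4], pitch=arr[:, 5],
        trial_id=f"{agent_id}-{dest.id}", subject_id=agent_id, source=source,
        atria_type=env.atria_type, destination_id=dest.id,
        meta={
            "complete": state.mode == "DONE",
            "explore_zone_targets": list(state.explore_targets),
            "initial_heading": float(initial_heading),
            "seed": int(seed),
        },
    )
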