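"""Cognitive-agent FSM, A* routing, and trial simulation."""

import math

import networkx as nx
import numpy as np
import pytest

import wayvis as wv
from wayvis.agents import AgentState, _choose_explore_target, perceive, plan_shortest_path
from wayvis.building import FloorGrid, NavGrid, Pose


def _random_grid(rng, n=8, p_wall=0.25):
    walk = rng.random((n, n)) > p_wall
    walk[0, 0] = walk[n - 1, n - 1] = True
    fg = FloorGrid(origin=(0.0, 0.0), nx=n, ny=n, walkable=walk, elevation=0.0)
    return NavGrid(resolution=1.0, floors=[fg])


class TestAStar:
    def test_straight_line_on_empty_grid(self):
        fg = FloorGrid((0, 0), 5, 5, np.ones((5, 5), bool), 0.0)
        grid = NavGrid(1.0, [fg])
        path = plan_shortest_path(grid, (0, 0, 0), (0, 0, 4))
        assert len(path) == 5  # 4 unit moves

    def test_wall_detour_cost_equals_dijkstra(self):
        walk = np.ones((5, 5), bool)
        walk[2, 0:3] = False  # 3-cell wall
        grid = NavGrid(1.0, [FloorGrid((0, 0), 5, 5, walk, 0.0)])
        g = grid.graph()
        cost_astar = nx.path_weight(g, plan_shortest_path(grid, (0, 0, 0), (0, 4, 0)),
                                    "weight")
        cost_dijkstra = nx.dijkstra_path_length(g, (0, 0, 0), (0, 4, 0))
        assert cost_astar == pytest.approx(cost_dijkstra, abs=1e-9)

    def test_matches_dijkstra_on_random_grids(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 25:
            grid = _random_grid(rng)
            g = grid.graph()
            s, t = (0, 0, 0), (0, 7, 7)
            if not (g.has_node(s) and g.has_node(t) and nx.has_path(g, s, t)):
                continue
            cost = nx.path_weight(g, plan_shortest_path(grid, s, t), "weight")
            assert cost == pytest.approx(nx.dijkstra_path_length(g, s, t), abs=1e-9)
            checked += 1

    def test_unreachable_goal_raises(self):
        walk = np.ones((5, 5), bool)
        walk[2, :] = False
        grid = NavGrid(1.0, [FloorGrid((0, 0), 5, 5, walk, 0.0)])
        with pytest.raises(nx.NetworkXNoPath):
            plan_shortest_path(grid, (0, 0, 0), (0, 4, 4))

    def test_cross_floor_path_uses_escalator_link_once(self, env_centralized,
                                                      nav_grid):
        ent = nav_grid.nearest_cell(0, env_centralized.entrance.xy)
        dest = env_centralized.destination("F2-forward-left")
        goal = nav_grid.nearest_cell(1, dest.approach_point())
        path = plan_shortest_path(nav_grid, ent, goal)
        floors = [c[0] for c in path]
        switches = sum(1 for a, b in zip(floors, floors[1:]) if a != b)
        assert switches == 1


class TestFSM:
    def test_spawn_with_destination_in_sight_moves_to_escalator(self, world,
                                                                env_centralized):
        dest = env_centralized.destination("F2-forward-left")
        st = AgentState(pose=Pose(env_centralized.entrance.x, 0.0, 0.0, yaw=0.0),
                        floor=0)
        percept = perceive(st, world, dest)
        assert percept.destination_in_sight
        st = wv.agent_step(st, percept, world, dest)
        assert st.mode == "MOVE_TO_ESCALATOR"

    def test_spawn_facing_away_explores(self, world, env_centralized):
        dest = env_centralized.destination("F2-forward-left")
        st = AgentState(pose=Pose(env_centralized.entrance.x, 0.0, 0.0, yaw=180.0),
                        floor=0)
        percept = perceive(st, world, dest)
        assert not percept.destination_in_sight
        st = wv.agent_step(st, percept, world, dest)
        assert st.mode == "EXPLORE"

    def test_backwards_destination_never_visible_at_spawn(self, world,
                                                          env_centralized):
        dest = env_centralized.destination("F2-backward-left")
        for yaw in (-180.0, -90.0, 0.0, 90.0):
            st = AgentState(pose=Pose(env_centralized.entrance.x, 0.0, 0.0,
                                      yaw=yaw), floor=0)
            assert not perceive(st, world, dest).destination_in_sight

    def test_explore_target_skips_visited_zone(self, world):
        st = AgentState(pose=Pose(16.5, 0.5, 0.0, yaw=0.0), floor=0)
        dest = world.env.destination("F2-backward-left")
        percept = perceive(st, world, dest)
        free = _choose_explore_target(st, percept, world)
        zone_free = world.zones[world.cell_zone[0][
            world.cells[0].index(free)]].id
        st2 = AgentState(pose=Pose(16.5, 0.5, 0.0, yaw=0.0), floor=0,
                         visited_zones={zone_free})
        other = _choose_explore_target(st2, percept, world)
        assert other is not None
        zone_other = world.zones[world.cell_zone[0][
            world.cells[0].index(other)]].id
        assert zone_other != zone_free


class TestTrials:
    def test_determinism(self, env_centralized, nav_grid, drift_field, world):
        a = wv.run_trial("cognitive", env_centralized, nav_grid, drift_field,
                         "F2-backward-left", initial_heading=37.0, world=world)
        b = wv.run_trial("cognitive", env_centralized, nav_grid, drift_field,
                         "F2-backward-left", initial_heading=37.0, world=world)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.yaw, b.yaw)

    def test_speed_cap_per_logged_step(self, env_centralized, nav_grid,
                                       drift_field, world):
        tr = wv.run_trial("cognitive", env_centralized, nav_grid, drift_field,
                          "F2-backward-right", initial_heading=120.0, world=world)
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        dt = np.diff(tr.t)
        assert np.all(steps <= 1.3 * dt + 1e-9)

    def test_zone_memory_no_repeated_explore_targets(self, env_centralized,
                                                     nav_grid, drift_field, world):
        for h in (-150.0, -60.0, 40.0, 170.0):
            tr = wv.run_trial("cognitive", env_centralized, nav_grid, drift_field,
                              "F2-backward-left", initial_heading=h, world=world)
            targets = tr.meta["explore_zone_targets"]
            assert len(targets) == len(set(targets))

    def test_trials_terminate(self, env_centralized, nav_grid, drift_field, world):
        for dest in ("F2-forward-right", "F2-backward-right"):
            tr = wv.run_trial("cognitive", env_centralized, nav_grid, drift_field,
                              dest, initial_heading=-135.0, world=world)
            assert tr.meta["complete"]

    def test_shortest_path_time_invariant_across_destinations(
            self, env_centralized, nav_grid, drift_field, world):
        times = []
        for dest in ("F2-forward-left", "F2-forward-right",
                     "F2-backward-left", "F2-backward-right"):
            tr = wv.run_trial("shortest_path", env_centralized, nav_grid,
                              drift_field, dest, initial_heading=0.0, world=world)
            w = wv.extract_analysis_window(tr, env_centralized)
            times.append(w.duration)
        assert float(np.std(times)) < 1e-9

    def test_cognitive_forward_faster_than_backward_same_heading(
            self, env_centralized, nav_grid, drift_field, world):
        def tte(dest, h):
            tr = wv.run_trial("cognitive", env_centralized, nav_grid,
                              drift_field, dest, initial_heading=h, world=world)
            return wv.extract_analysis_window(tr, env_centralized).duration

        for h in (0.0, 90.0):
            assert tte("F2-forward-left", h) < tte("F2-backward-left", h)

    def test_bad_agent_type_rejected(self, env_centralized, nav_grid,
                                     drift_field, world):
        with pytest.raises(ValueError):
            wv.run_trial("random_walk", env_centralized, nav_grid, drift_field,
                         "F2-forward-left", 0.0, world=world)
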