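"""Analysis window extraction and the four behavioural measures."""

import math

import numpy as np
import pytest
from shapely.geometry import box

import wayvis as wv
from wayvis.building import (
    BuildingParams, Destination, Environment, Escalator, FloorPlan, Pose,
)
from wayvis.measures import IncompleteTrialError
from wayvis.trajectory import Trajectory


def _measure_env(base=(13.0, 0.0)):
    """Flat open test floor with an escalator base and a distant visible door."""
    door = Destination("door", 0, "x", 20.0, -1.0, 1.0, 0.0, 2.0, -1,
                       "entrance-forward-facing", "left")
    fl = FloorPlan(box(-5, -20, 40, 20), 0.0, 10.0, box(-5, -20, 40, 20))
    return Environment("centralized", BuildingParams(entrance_x=0.0),
                       [fl], [], [], [door],
                       Escalator((base[0], base[1], 0.0), (base[0] + 3, base[1], 3.0)),
                       Pose(0, 0, 0)), door


def _straight_traj(speed=1.3, distance=13.0, dt=0.1, yaw=0.0):
    n = int(math.ceil(distance / (speed * dt))) + 1
    x = np.minimum(np.arange(n) * speed * dt, distance)
    return Trajectory(t=np.arange(n) * dt, x=x, y=np.zeros(n),
                      z=np.full(n, 1.7), yaw=np.full(n, yaw),
                      pitch=np.zeros(n), trial_id="s")


class TestAnalysisWindow:
    def test_straight_walk_duration(self):
        env, _ = _measure_env(base=(13.0, 0.0))
        tr = _straight_traj()
        w = wv.extract_analysis_window(tr, env, arrival_radius=0.5)
        # (13 - 0.5) / 1.3 s, up to one sampling interval
        assert w.duration == pytest.approx((13 - 0.5) / 1.3, abs=0.1)

    def test_window_ends_at_first_arrival(self):
        env, _ = _measure_env(base=(5.0, 0.0))
        # out to x=8, back to 0, out again: first crossing of the 0.5 m radius
        xs = np.concatenate([np.linspace(0, 8, 41), np.linspace(8, 0, 41)[1:],
                             np.linspace(0, 8, 41)[1:]])
        tr = Trajectory(t=np.arange(len(xs)) * 0.1, x=xs, y=np.zeros(len(xs)),
                        z=np.full(len(xs), 1.7), yaw=np.zeros(len(xs)),
                        pitch=np.zeros(len(xs)))
        w = wv.extract_analysis_window(tr, env, arrival_radius=0.5)
        assert w.x[-1] >= 4.5
        assert len(w) < 30  # well before the loop returns

    def test_never_reaching_base_is_incomplete(self):
        env, _ = _measure_env(base=(30.0, 0.0))
        with pytest.raises(IncompleteTrialError):
            wv.extract_analysis_window(_straight_traj(distance=5.0), env)

    def test_not_starting_at_entrance_rejected(self):
        env, _ = _measure_env()
        tr = _straight_traj()
        tr.x = tr.x + 8.0
        with pytest.raises(ValueError, match="entrance"):
            wv.extract_analysis_window(tr, env)


class TestMeasures:
    def test_hand_built_five_sample_window(self):
        env, door = _measure_env(base=(10.0, 0.0))
        tr = Trajectory(
            t=[0, 0.5, 1.0, 1.5, 2.0],
            x=[0, 1, 2, 3, 4], y=[0, 0.5, 0.5, 0, 0],
            z=[1.0] * 5, yaw=[0, 30, -20, 10, 0], pitch=[0, 2, -1, 3, 0])
        m = wv.compute_measures(tr, env, door, fov=wv.HUMAN_FOV)
        assert m.time_to_escalator == pytest.approx(2.0, abs=1e-9)
        assert m.avg_vertical_head_movement == pytest.approx(3.0, abs=1e-9)
        # hand-computed: mean of cos(yaw_i - atan2(-y_i, 10 - x_i))
        assert m.avg_cosine_similarity == pytest.approx(0.9561924094552682, abs=1e-9)
        # unobstructed door inside the FOV from every sample
        assert m.avg_destination_visibility == pytest.approx(1.0, abs=1e-9)

    def test_cosine_attains_plus_and_minus_one(self):
        env, door = _measure_env(base=(10.0, 0.0))
        toward = Trajectory(t=[0, 1], x=[0, 1], y=[0, 0], z=[1.7] * 2,
                            yaw=[0, 0], pitch=[0, 0])
        away = Trajectory(t=[0, 1], x=[0, 1], y=[0, 0], z=[1.7] * 2,
                          yaw=[180, 180], pitch=[0, 0])
        assert wv.compute_measures(toward, env, door, fov=None) \
            .avg_cosine_similarity == pytest.approx(1.0)
        assert wv.compute_measures(away, env, door, fov=None) \
            .avg_cosine_similarity == pytest.approx(-1.0)

    def test_constant_pitch_zero_head_movement(self):
        env, door = _measure_env()
        tr = _straight_traj()
        tr.pitch = np.full(len(tr), 12.5)
        m = wv.compute_measures(tr, env, door, fov=None)
        assert m.avg_vertical_head_movement == 0.0

    def test_head_movement_nonnegative_and_zero_iff_constant(self):
        env, door = _measure_env()
        rng = np.random.default_rng(7)
        tr = _straight_traj()
        tr.pitch = rng.normal(0, 2, len(tr))
        m = wv.compute_measures(tr, env, door, fov=None)
        assert m.avg_vertical_head_movement > 0

    def test_cosine_ranks_inverse_to_angular_deviation(self):
        # constant-deviation windows: cosine ranking must invert the
        # absolute-angle ranking exactly
        env, door = _measure_env(base=(1000.0, 0.0))
        angles = [5.0, 25.0, 60.0, 110.0, 170.0]
        cos_means, ang_means = [], []
        for a in angles:
            tr = Trajectory(t=[0, 1, 2], x=[0, 0.1, 0.2], y=[0, 0, 0],
                            z=[1.7] * 3, yaw=[a] * 3, pitch=[0] * 3)
            m = wv.compute_measures(tr, env, door, fov=None)
            cos_means.append(m.avg_cosine_similarity)
            ang_means.append(a)
        assert np.all(np.argsort(cos_means)[::-1] == np.argsort(ang_means))

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(t=[0.0], x=[0], y=[0], z=[0], yaw=[0], pitch=[0])

    def test_time_and_cos_invariant_under_resampling(self, env_centralized):
        """Piecewise-linear paths keep time/cosine/visibility (not the
        per-sample pitch increment) under 2x finer resampling."""
        from wayvis.synthetic import SyntheticDesign, generate_synthetic_trials
        des = SyntheticDesign(n_participants=2, blocks=1, seed=5)
        tr = [t for t in generate_synthetic_trials(des, [env_centralized])
              if t.destination_id.startswith("F2")][0]
        dest = env_centralized.destination(tr.destination_id)
        w = wv.extract_analysis_window(tr, env_centralized)
        t2 = np.sort(np.concatenate([w.t, 0.5 * (w.t[:-1] + w.t[1:])]))
        fine = Trajectory(
            t=t2, x=np.interp(t2, w.t, w.x), y=np.interp(t2, w.t, w.y),
            z=np.interp(t2, w.t, w.z), yaw=np.interp(t2, w.t, w.yaw),
            pitch=np.interp(t2, w.t, w.pitch))
        m1 = wv.compute_measures(w, env_centralized, dest, n_rays=25)
        m2 = wv.compute_measures(fine, env_centralized, dest, n_rays=25)
        assert m2.time_to_escalator == pytest.approx(m1.time_to_escalator, rel=0.01)
        assert m2.avg_cosine_similarity == pytest.approx(m1.avg_cosine_similarity,
                                                         rel=0.01)
        assert m2.avg_destination_visibility == pytest.approx(
            m1.avg_destination_visibility, rel=0.01, abs=1e-4)

    def test_visibility_stride_converges(self, env_centralized):
        from wayvis.synthetic import SyntheticDesign, generate_synthetic_trials
        des = SyntheticDesign(n_participants=2, blocks=1, seed=6)
        tr = [t for t in generate_synthetic_trials(des, [env_centralized])
              if "forward" in t.destination_id and t.destination_id.startswith("F2")][0]
        dest = env_centralized.destination(tr.destination_id)
        w = wv.extract_analysis_window(tr, env_centralized)
        m1 = wv.compute_measures(w, env_centralized, dest, n_rays=25,
                                 visibility_stride=1)
        m5 = wv.compute_measures(w, env_centralized, dest, n_rays=25,
                                 visibility_stride=5)
        assert m5.avg_destination_visibility == pytest.approx(
            m1.avg_destination_visibility, rel=0.05)


class TestVisibilityCondition:
    def _table(self, values):
        import pandas as pd
        return pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(len(values))],
            "block": [1] * len(values),
            "avg_destination_visibility": values,
        })

    def test_segmentation_rule(self):
        seg = wv.segment_visibility_condition(self._table([0.0, 0.008, 0.08, 0.0]))
        assert list(seg["condition"]) == ["NV", "V", "V", "NV"]
        assert seg.attrs["n_nv"] == 2 and seg.attrs["n_v"] == 2

    def test_all_zero_yields_empty_visible_set(self):
        seg = wv.segment_visibility_condition(self._table([0.0, 0.0, 0.0]))
        assert seg.attrs["n_v"] == 0

    def test_matching_equalises_counts(self):
        rng = np.random.default_rng(3)
        seg = wv.segment_visibility_condition(
            self._table([0.0] * 10 + [0.01] * 6))
        matched = wv.match_conditions(seg, rng)
        assert (matched["condition"] == "NV").sum() == \
            (matched["condition"] == "V").sum() == 6
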