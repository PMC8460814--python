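"""Per-trial wayfinding behavioural measures and visibility conditions.

All measures are evaluated over the *analysis window*: the trajectory prefix
from the trial start until the first arrival at the bottom step of the
escalator.  The four measures are

* ``time_to_escalator`` — window duration in seconds,
* ``avg_vertical_head_movement`` — mean absolute change in camera pitch
  between consecutive samples (degrees),
* ``avg_cosine_similarity`` — mean cosine between the heading and the
  direction to the escalator base (1 = heading straight at it),
* ``avg_destination_visibility`` — mean ray-cast visible fraction of the
  destination door over the window (0..1).

Trials with zero average destination visibility form the non-visible (NV)
condition; all others are visible (V).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .building import Destination, Environment
from .trajectory import Trajectory
from .visibility import FieldOfView, HUMAN_FOV, visibility_fractions


class IncompleteTrialError(ValueError):
    """The trajectory never reaches the escalator base."""


@dataclass(frozen=True)
class BehavioralMeasures:
    time_to_escalator: float
    avg_vertical_head_movement: float
    avg_cosine_similarity: float
    avg_destination_visibility: float

    def __post_init__(self) -> None:
        if self.avg_vertical_head_movement < 0:
            raise ValueError("vertical head movement cannot be negative")
        if not -1.0 - 1e-9 <= self.avg_cosine_similarity <= 1.0 + 1e-9:
            raise ValueError("cosine similarity outside [-1, 1]")
        if not np.isnan(self.avg_destination_visibility):
            if not -1e-12 <= self.avg_destination_visibility <= 1.0 + 1e-12:
                raise ValueError("visibility outside [0, 1]")


def extract_analysis_window(traj: Trajectory, env: Environment,
                            arrival_radius: float = 0.5) -> Trajectory:
    """Trajectory prefix ending at the first arrival at the escalator base.

    Arrival means the horizontal distance to the base point drops to
    ``arrival_radius`` or less.  Raises ``IncompleteTrialError`` when the base
    is never reached, and ``ValueError`` when the trial does not start at the
    entrance.
    """
    if env.escalator is None:
        raise ValueError("environment has no escalator")
    start = np.array([traj.x[0], traj.y[0]])
    if np.linalg.norm(start - env.entrance.xy) > max(2.0 * arrival_radius, 1.0):
        raise ValueError("trajectory does not start at the entrance")
    d = np.hypot(traj.x - env.escalator.base[0], traj.y - env.escalator.base[1])
    hits = np.nonzero(d <= arrival_radius)[0]
    if len(hits) == 0:
        raise IncompleteTrialError(
            f"trial {traj.trial_id!r} never reaches the escalator base")
    return traj.slice(int(hits[0]))


def heading_cosines(window: Trajectory, base_xy: np.ndarray,
                    plane: str = "horizontal") -> np.ndarray:
    """Cosine between the heading and the direction to the escalator base.

    By default both vectors are projected onto the horizontal plane, so that
    a level gaze aimed at the base scores exactly 1.  ``plane='3d'`` compares
    the full camera-forward vector with the 3D vector to the base point.
    """
    if plane == "horizontal":
        yaw = np.radians(window.yaw)
        h = np.column_stack([np.cos(yaw), np.sin(yaw)])
        v = base_xy[None, :] - window.xy
    elif plane == "3d":
        yaw = np.radians(window.yaw)
        pitch = np.radians(window.pitch)
        h = np.column_stack([np.cos(pitch) * np.cos(yaw),
                             np.cos(pitch) * np.sin(yaw),
                             np.sin(pitch)])
        base3 = np.array([base_xy[0], base_xy[1], 0.0])
        v = base3[None, :] - window.positions
    else:
        raise ValueError("plane must be 'horizontal' or '3d'")
    norms = np.linalg.norm(v, axis=1)
    norms[norms < 1e-12] = 1.0  # standing on the base: define cosine via heading only
    v = v / norms[:, None]
    return np.clip(np.einsum("ij,ij->i", h, v), -1.0, 1.0)


def compute_measures(window: Trajectory, env: Environment, dest: Destination,
                     fov: FieldOfView | None = HUMAN_FOV,
                     n_rays: int = 100, visibility_stride: int = 1,
                     cosine_plane: str = "horizontal") -> BehavioralMeasures:
    """The four behavioural measures of one analysis window.

    ``fov=None`` skips the (comparatively expensive) destination-visibility
    ray casting and reports NaN for it — useful for agent trials where only
    time and cosine similarity are compared.  ``visibility_stride`` scores
    every k-th sample; measures converge quickly in the stride because
    consecutive poses are highly correlated.
    """
    if len(window) < 2:
        raise ValueError("window must contain at least 2 samples")
    time_to_escalator = window.duration
    avg_vhm = float(np.mean(np.abs(np.diff(window.pitch))))
    cosines = heading_cosines(window, env.escalator.base_xy, plane=cosine_plane)
    avg_cos = float(np.mean(cosines))
    if fov is None:
        avg_vis = float("nan")
    else:
        idx = np.arange(0, len(window), max(1, int(visibility_stride)))
        fracs = visibility_fractions(
            window.positions[idx], dest, env, fov,
            yaws=window.yaw[idx], pitches=window.pitch[idx], n_rays=n_rays)
        avg_vis = float(np.mean(fracs))
    return BehavioralMeasures(
        time_to_escalator=time_to_escalator,
        avg_vertical_head_movement=avg_vhm,
        avg_cosine_similarity=avg_cos,
        avg_destination_visibility=avg_vis,
    )


def measures_table(trajs: list[Trajectory], env: Environment,
                   fov: FieldOfView | None = HUMAN_FOV,
                   arrival_radius: float = 0.5, n_rays: int = 100,
                   visibility_stride: int = 1,
                   analyzed_floor: int | None = 1) -> pd.DataFrame:
    """Measures for a batch of trials: one row per complete analysed trial.

    ``analyzed_floor`` keeps only trials towards destinations on that floor
    (the study analyses between-floor trials only); ``None`` keeps all.
    Incomplete trials (escalator never reached) are dropped and counted in
    the ``attrs['n_incomplete']`` of the result.
    """
    rows = []
    n_incomplete = 0
    for tr in trajs:
        dest = env.destination(tr.destination_id)
        if analyzed_floor is not None and dest.floor != analyzed_floor:
            continue
        try:
            window = extract_analysis_window(tr, env, arrival_radius)
        except IncompleteTrialError:
            n_incomplete += 1
            continue
        m = compute_measures(window, env, dest, fov=fov, n_rays=n_rays,
                             visibility_stride=visibility_stride)
        rows.append({
            "trial_id": tr.trial_id, "subject_id": tr.subject_id,
            "source": tr.source, "block": tr.block, "session": tr.session,
            "atria_type": tr.atria_type, "destination_id": tr.destination_id,
            "facing": dest.facing,
            "time_to_escalator": m.time_to_escalator,
            "avg_vertical_head_movement": m.avg_vertical_head_movement,
            "avg_cosine_similarity": m.avg_cosine_similarity,
            "avg_destination_visibility": m.avg_destination_visibility,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_incomplete"] = n_incomplete
    return df


def segment_visibility_condition(measures: pd.DataFrame) -> pd.DataFrame:
    """Label trials NV (avg visibility exactly zero) or V (positive).

    Returns a copy with a ``condition`` column; counts are stored in
    ``attrs['n_nv']`` / ``attrs['n_v']``.
    """
    out = measures.copy()
    out["condition"] = np.where(
        out["avg_destination_visibility"] > 0.0, "V", "NV")
    out.attrs["n_nv"] = int((out["condition"] == "NV").sum())
    out.attrs["n_v"] = int((out["condition"] == "V").sum())
    return out


def match_conditions(segmented: pd.DataFrame, rng: np.random.Generator,
                     keys: tuple[str, ...] = ("subject_id", "block")) -> pd.DataFrame:
    """Optionally subsample the larger condition to match the smaller one.

    Within each stratum defined by ``keys``, trials of the larger condition
    are randomly dropped until both conditions have equal counts overall.
    The study reports matched NV/V sets without stating its matching rule;
    this random stratified matcher is one reasonable realisation and is not
    claimed canonical.
    """
    n_nv = int((segmented["condition"] == "NV").sum())
    n_v = int((segmented["condition"] == "V").sum())
    if n_nv == n_v:
        return segmented.copy()
    larger, n_drop = ("NV", n_nv - n_v) if n_nv > n_v else ("V", n_v - n_nv)
    pool = segmented.index[segmented["condition"] == larger].to_numpy()
    # drop spread across strata: shuffle within strata order then trim
    order = segmented.loc[pool].groupby(list(keys)).cumcount().to_numpy()
    shuffled = pool[np.lexsort((rng.permutation(len(pool)), order))][::-1]
    return segmented.drop(index=shuffled[:n_drop]).copy()
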