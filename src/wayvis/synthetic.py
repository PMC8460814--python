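"""Seeded synthetic "human-like" trial generator with known injected effects.

The generator emulates the study design — 69 participants, two between-
subject factors (atria type, session), three blocks of eight destinations —
and realises target values of the behavioural measures *geometrically*:

* Time to Escalator is controlled by a hesitation dwell at the entrance
  before walking the fixed entrance-to-escalator path at 1.3 m/s;
* Average Vertical Head Movement is an alternating pitch micro-oscillation
  whose step size equals the target mean absolute pitch change;
* Average Cosine Similarity is tuned by the heading held during the dwell
  (rotated away from the destination side), solved so the window mean hits
  the target, clamped to the geometrically feasible range;
* the visibility condition follows the destination's facing: forward-facing
  doors are visible through the atria during the walk (V), backwards-facing
  doors are occluded by the second-floor slab from the whole path (NV).

Targets follow a linear mixed model: measure intercepts and fixed effects
(visibility condition, block) are the injected parameters, participant
intercepts and residuals are Gaussian.  Atria-type and session effects are
zero by design.  Every trial is deterministic given the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .building import Environment, normalize_yaw
from .trajectory import Trajectory


@dataclass
class EffectSpec:
    """Injected generating parameters for one behavioural measure."""

    intercept: float
    visibility_effect: float  # added for V (visible) trials
    block_effect: float  # per 0-based block
    participant_sd: float
    residual_sd: float


@dataclass
class SyntheticDesign:
    """The emulated study design; defaults mirror the study's conditions."""

    n_participants: int = 69
    blocks: int = 3
    sessions: int = 2
    trials_per_block: int = 8  # 4 per floor
    time: EffectSpec = field(default_factory=lambda: EffectSpec(
        intercept=34.765, visibility_effect=-4.935, block_effect=-2.095,
        participant_sd=3.97, residual_sd=5.0))
    vertical_head_movement: EffectSpec = field(default_factory=lambda: EffectSpec(
        intercept=0.041, visibility_effect=-0.025, block_effect=-0.002,
        participant_sd=0.003, residual_sd=0.008))
    cosine: EffectSpec = field(default_factory=lambda: EffectSpec(
        intercept=0.723, visibility_effect=0.107, block_effect=0.039,
        participant_sd=0.05, residual_sd=0.06))
    dt: float = 0.1
    seed: int = 0
    include_first_floor: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.blocks < 1:
            raise ValueError("need at least 2 participants and 1 block")
        for cond in (0.0, 1.0):
            c = self.cosine.intercept + cond * self.cosine.visibility_effect
            if not -1.0 < c < 1.0:
                raise ValueError("cosine targets leave the [-1, 1] range")
        if self.time.intercept + min(0.0, self.time.visibility_effect) <= 0:
            raise ValueError("time targets must stay positive")

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.blocks * self.trials_per_block

    @property
    def n_analyzed(self) -> int:
        return self.n_participants * self.blocks * (self.trials_per_block // 2)


def _polyline_walk(waypoints: np.ndarray, speed: float, dt: float):
    """Positions and headings sampled along a polyline at constant speed."""
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = int(math.ceil(total / (speed * dt)))
    s = np.minimum((np.arange(1, n + 1)) * speed * dt, total)
    k = np.minimum(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
    frac = (s - cum[k]) / np.maximum(seg_len[k], 1e-12)
    pos = waypoints[k] + frac[:, None] * seg[k]
    yaw = np.degrees(np.arctan2(seg[k, 1], seg[k, 0]))
    return pos, yaw


class _PathCache:
    """Entrance-to-escalator walk shared by all second-floor trials."""

    def __init__(self, env: Environment, dt: float, arrival_radius: float = 0.5):
        p = env.params
        ex, ey = p.escalator_base
        start = np.array([p.entrance_x, 0.0])
        waypoints = np.array([
            start,
            [ex + 0.6, ey + 1.2],
            [ex + 0.2, ey + 0.1],
        ])
        self.pos, self.yaw = _polyline_walk(waypoints, 1.3, dt)
        base = np.array([ex, ey])
        d = np.hypot(self.pos[:, 0] - base[0], self.pos[:, 1] - base[1])
        hits = np.nonzero(d <= arrival_radius)[0]
        if len(hits) == 0:
            raise RuntimeError("generator path never reaches the escalator base")
        self.n_cut = int(hits[0]) + 1  # samples inside the analysis window
        self.base_dir = math.degrees(math.atan2(base[1] - start[1], base[0] - start[0]))
        # cosine contribution of the move phase within the window
        v = base[None, :] - self.pos[: self.n_cut]
        nv = np.linalg.norm(v, axis=1)
        nv[nv < 1e-12] = 1.0
        yawr = np.radians(self.yaw[: self.n_cut])
        h = np.column_stack([np.cos(yawr), np.sin(yawr)])
        self.cos_move = np.einsum("ij,ij->i", h, v / nv[:, None])
        self.start = start


def generate_synthetic_trials(design: SyntheticDesign,
                              envs) -> list[Trajectory]:
    """Generate the full emulated study.

    ``envs`` is one Environment or a sequence of (typically two) buildings;
    participants are assigned to the buildings in alternation, mirroring the
    between-subject atria manipulation.  Returns one trajectory per trial,
    first- and second-floor destinations alike (only second-floor trials are
    analysed downstream).
    """
    if isinstance(envs, Environment):
        envs = [envs]
    envs = list(envs)
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    dt = design.dt
    caches = [_PathCache(e, dt) for e in envs]
    eye = envs[0].params.eye_height
    esc = envs[0].escalator
    ramp_dir3 = (np.asarray(esc.top) - np.asarray(esc.base)) / esc.length

    specs = {"time": design.time, "vhm": design.vertical_head_movement,
             "cos": design.cosine}
    out: list[Trajectory] = []
    for pid in range(design.n_participants):
        env = envs[pid % len(envs)]
        cache = caches[pid % len(envs)]
        session = 1 if pid < design.n_participants // 2 else 2
        u = {k: rng.normal(0.0, s.participant_sd) for k, s in specs.items()}
        dests = [d for d in env.destinations
                 if design.include_first_floor or d.floor == 1]
        for b in range(design.blocks):
            order = rng.permutation(len(dests))
            for di in order:
                dest = dests[di]
                trial_id = f"P{pid:03d}-B{b + 1}-{dest.id}"
                if dest.floor == 1:
                    tr = _floor2_trial(design, env, cache, dest, rng, u, b,
                                       eye, esc, ramp_dir3)
                else:
                    tr = _floor1_trial(design, env, dest, rng, eye)
                tr.trial_id = trial_id
                tr.subject_id = f"P{pid:03d}"
                tr.source = "synthetic"
                tr.block = b + 1
                tr.session = session
                tr.atria_type = env.atria_type
                tr.destination_id = dest.id
                out.append(tr)
    return out


def _floor2_trial(design, env, cache, dest, rng, u, block0, eye, esc, ramp_dir3):
    dt = design.dt
    visible = dest.facing == "entrance-forward-facing"
    tgt = {}
    for key, spec in (("time", design.time), ("vhm", design.vertical_head_movement),
                      ("cos", design.cosine)):
        tgt[key] = (spec.intercept + u[key] + block0 * spec.block_effect
                    + (spec.visibility_effect if visible else 0.0)
                    + rng.normal(0.0, spec.residual_sd))
    tgt["vhm"] = max(tgt["vhm"], 5e-4)

    n_cut = cache.n_cut
    move_time = n_cut * dt
    n_dwell = max(0, int(round((tgt["time"] - move_time) / dt)))
    n_window = n_dwell + n_cut
    # dwell heading that realises the cosine target, rotated away from the
    # destination's side so backwards-facing doors stay out of view
    if n_dwell > 0:
        c_d = (tgt["cos"] * n_window - cache.cos_move.sum()) / n_dwell
        c_d = float(np.clip(c_d, math.cos(math.radians(130.0)), 1.0))
        theta = math.degrees(math.acos(c_d))
    else:
        theta = 0.0
    sign = -1.0 if dest.side == "left" else 1.0
    yaw_dwell = normalize_yaw(cache.base_dir + sign * theta)

    n_move = len(cache.pos)
    n_tail = 8
    n = n_dwell + n_move + n_tail
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    z = np.full(n, eye)
    yaw = np.empty(n)
    # hesitation is paced, not frozen: the avatar shuffles forward and back
    # along its dwell heading at 0.3 m/s, so longer hesitation also means a
    # longer walked path (time and distance stay concordant across conditions)
    amp = 0.6
    phase = (np.arange(n_dwell) * 0.3 * dt) % (2 * amp)
    off = np.where(phase <= amp, phase, 2 * amp - phase)
    ur = math.radians(yaw_dwell)
    x[:n_dwell] = cache.start[0] + off * math.cos(ur)
    y[:n_dwell] = cache.start[1] + off * math.sin(ur)
    yaw[:n_dwell] = yaw_dwell
    x[n_dwell:n_dwell + n_move] = cache.pos[:, 0]
    y[n_dwell:n_dwell + n_move] = cache.pos[:, 1]
    yaw[n_dwell:n_dwell + n_move] = cache.yaw
    # short tail up the escalator ramp (outside the analysis window)
    s = (np.arange(1, n_tail + 1)) * 1.3 * dt
    s = np.minimum(s, esc.length)
    ramp = np.asarray(esc.base)[None, :] + s[:, None] * ramp_dir3[None, :]
    x[n_dwell + n_move:] = ramp[:, 0]
    y[n_dwell + n_move:] = ramp[:, 1]
    z[n_dwell + n_move:] = ramp[:, 2] + eye
    yaw[n_dwell + n_move:] = math.degrees(math.atan2(ramp_dir3[1], ramp_dir3[0]))
    pitch = (np.arange(n) % 2) * tgt["vhm"]
    return Trajectory(t=t, x=x, y=y, z=z, yaw=yaw, pitch=pitch)


def _floor1_trial(design, env, dest, rng, eye):
    """First-floor filler trial (never analysed): a direct walk to the door."""
    dt = design.dt
    start = np.array([env.params.entrance_x, 0.0])
    goal = dest.approach_point()[:2]
    pos, yaw = _polyline_walk(np.array([start, goal]), 1.3, dt)
    n_dwell = int(rng.integers(5, 30))
    n = n_dwell + len(pos)
    t = np.arange(n) * dt
    x = np.concatenate([np.full(n_dwell, start[0]), pos[:, 0]])
    y = np.concatenate([np.full(n_dwell, start[1]), pos[:, 1]])
    yaws = np.concatenate([np.zeros(n_dwell), yaw])
    pitch = (np.arange(n) % 2) * 0.02
    return Trajectory(t=t, x=x, y=y, z=np.full(n, eye), yaw=yaws, pitch=pitch)
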