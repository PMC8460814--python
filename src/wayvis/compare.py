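"""Monte-Carlo simulation experiments and agent-vs-human comparison metrics.

Each Monte-Carlo sample is one simulated trial whose random variable is the
agent's initial heading (uniform on the circle).  Samples are organised as
agents: agent *i* draws one heading and runs every destination in the
configured set, so the per-agent random intercept of the difference model is
identified.  Agent behaviour is compared to human benchmarks through the L1
(absolute) differences in Time to Escalator and Average Cosine Similarity
against the per-destination human mean, through Gaussian KDE rasters of path
distributions, and optionally through dynamic time warping of paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .agents import AgentParams, AgentWorld, run_trial
from .building import Environment, NavGrid, Zone, decompose_zones
from .stats import LmerResult, fit_lmer
from .trajectory import Trajectory
from .visibility import DriftField

#: the study's total sample count per simulation experiment
DEFAULT_N_SAMPLES = 1600

FLOOR2_DESTINATIONS = ("F2-forward-left", "F2-forward-right",
                       "F2-backward-left", "F2-backward-right")


@dataclass
class MonteCarloConfig:
    agent_type: str = "cognitive"
    n_samples: int = DEFAULT_N_SAMPLES
    destinations: tuple[str, ...] = FLOOR2_DESTINATIONS
    heading_low: float = -180.0
    heading_high: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_samples % len(self.destinations) != 0:
            raise ValueError("n_samples must be divisible by the destination count "
                             "(each agent runs every destination once)")

    @property
    def n_agents(self) -> int:
        return self.n_samples // len(self.destinations)


def draw_headings(cfg: MonteCarloConfig) -> np.ndarray:
    """The per-agent initial headings implied by a config (uniform circle)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    return rng.uniform(cfg.heading_low, cfg.heading_high, size=cfg.n_agents)


def run_monte_carlo(cfg: MonteCarloConfig, env: Environment, grid: NavGrid,
                    field: DriftField, zones: list[Zone] | None = None,
                    world: AgentWorld | None = None,
                    params: AgentParams | None = None) -> list[Trajectory]:
    """Run the configured simulation experiment; reproducible from the seed."""
    if world is None:
        if zones is None:
            zones = decompose_zones(env)
        world = AgentWorld(env, grid, zones, field, params=params)
    headings = draw_headings(cfg)
    out: list[Trajectory] = []
    for a, h in enumerate(headings):
        agent_id = f"{cfg.agent_type}-{a:04d}"
        for dest_id in cfg.destinations:
            tr = run_trial(cfg.agent_type, env, grid, field, dest_id,
                           initial_heading=float(h), seed=cfg.seed,
                           world=world, agent_id=agent_id)
            tr.block = 1
            tr.session = 1
            out.append(tr)
    return out


def benchmark_differences(agent_measures: pd.DataFrame,
                          human_measures: pd.DataFrame,
                          stat: str = "mean") -> pd.DataFrame:
    """Per-trial absolute deviations from per-destination human benchmarks.

    The benchmark for each destination is the mean (or median) of the human
    trials towards it; agent trials towards destinations with no human trial
    are excluded.  Returns one row per agent trial with ``diff_time`` and
    ``diff_cos``.
    """
    agg = {"mean": "mean", "median": "median"}[stat]
    bench = human_measures.groupby("destination_id")[
        ["time_to_escalator", "avg_cosine_similarity"]].agg(agg)
    rows = []
    for _, r in agent_measures.iterrows():
        if r["destination_id"] not in bench.index:
            continue
        b = bench.loc[r["destination_id"]]
        rows.append({
            "agent_id": r["subject_id"],
            "agent_type": r["source"],
            "destination_id": r["destination_id"],
            "diff_time": abs(r["time_to_escalator"] - b["time_to_escalator"]),
            "diff_cos": abs(r["avg_cosine_similarity"] - b["avg_cosine_similarity"]),
        })
    return pd.DataFrame(rows)


def agent_difference_lmer(diffs: pd.DataFrame, response: str,
                          reml: bool = True) -> LmerResult:
    """``DifferenceInMeasure ~ AgentType + (1 | Agent)``.

    The cognitive agent is the reference level, so the reported coefficient is
    the shortest-path agent's excess difference from human behaviour.
    """
    df = pd.DataFrame({
        "y": diffs[response].to_numpy(),
        "to_shortest": (diffs["agent_type"] == "shortest_path_agent").astype(float),
        "agent": diffs["agent_id"],
    })
    res = fit_lmer(df, "y", ["to_shortest"], group="agent", reml=reml)
    res.table.index = ["Intercept", "AgentType(to shortest)"]
    return res


@dataclass
class DensityRaster:
    """Normalised spatial density of path samples on a regular grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # (nx, ny), integrates to ~1 over the extent
    bandwidth: float | str

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0])
                     * (self.y_edges[1] - self.y_edges[0]))

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)

    @property
    def mode_xy(self) -> np.ndarray:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return np.array([
            0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
            0.5 * (self.y_edges[j] + self.y_edges[j + 1]),
        ])


def spatial_kde(trajs: list[Trajectory],
                extent: tuple[float, float, float, float],
                resolution: float = 0.5,
                bandwidth: float | str = "scott") -> DensityRaster:
    """Gaussian KDE over the horizontal positions of all trajectory samples.

    The raster is renormalised to integrate to 1 over the extent, so rasters
    with different extents remain comparable.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    pts = np.vstack([tr.xy for tr in trajs])
    x0, y0, x1, y1 = extent
    try:
        kde = gaussian_kde(pts.T, bw_method=bandwidth)
    except np.linalg.LinAlgError:
        # degenerate cloud (e.g. all samples coincide): isotropic kernel
        h = bandwidth if isinstance(bandwidth, (int, float)) else 0.5 * resolution
        mu = pts.mean(axis=0)

        def kde(q):  # noqa: F811 - same call signature as gaussian_kde
            d2 = ((q[0] - mu[0]) ** 2 + (q[1] - mu[1]) ** 2) / (h * h)
            return np.exp(-0.5 * d2) / (2 * np.pi * h * h)
    xe = np.arange(x0, x1 + resolution / 2, resolution)
    ye = np.arange(y0, y1 + resolution / 2, resolution)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell = resolution * resolution
    total = dens.sum() * cell
    if total <= 0:
        raise ValueError("density vanished on the requested extent")
    return DensityRaster(x_edges=xe, y_edges=ye, density=dens / total,
                         bandwidth=bandwidth)


def dtw_distance(a: Trajectory | np.ndarray, b: Trajectory | np.ndarray) -> float:
    """Classic dynamic-time-warping distance on 2D horizontal positions.

    Local cost is the Euclidean distance between matched points; no warping
    window is applied (trajectories sampled at 0.2 s are short).  Symmetric,
    and zero exactly for identical paths.
    """
    pa = a.xy if isinstance(a, Trajectory) else np.atleast_2d(np.asarray(a, float))
    pb = b.xy if isinstance(b, Trajectory) else np.atleast_2d(np.asarray(b, float))
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("both trajectories must be non-empty")
    n, m = len(pa), len(pb)
    cost = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        prev = acc[i - 1]
        cur = acc[i]
        for j in range(1, m + 1):
            cur[j] = cost[i - 1, j - 1] + min(prev[j], cur[j - 1], prev[j - 1])
    return float(acc[n, m])
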