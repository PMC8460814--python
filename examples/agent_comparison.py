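"""Cognitive vs shortest-path agents against human-like benchmarks.

Runs a small paired Monte-Carlo experiment (random initial headings), shows
the visibility signature in the cognitive agent's Time to Escalator, and
fits the agent-difference mixed model against synthetic human benchmarks.
"""

import pandas as pd

import wayvis as wv
from wayvis.compare import MonteCarloConfig
from wayvis.synthetic import SyntheticDesign, generate_synthetic_trials

env = wv.build_building("centralized")
grid = wv.build_nav_grid(env, resolution=1.0)
field = wv.build_drift_field(grid, env)
world = wv.AgentWorld(env, grid, wv.decompose_zones(env), field)

measures = {}
for agent in ("cognitive", "shortest_path"):
    cfg = MonteCarloConfig(agent, n_samples=32, seed=11)
    trajs = wv.run_monte_carlo(cfg, env, grid, field, world=world)
    measures[agent] = wv.measures_table(trajs, env, fov=None)
    by_facing = measures[agent].groupby("facing")["time_to_escalator"].mean()
    print(f"{agent:14s} mean Time to Escalator: "
          + ", ".join(f"{k.split('-')[1]}-facing {v:.1f} s"
                      for k, v in by_facing.items()))
print("-> the cognitive agent is faster when the destination is visible from "
      "the start; the shortest-path agent cannot tell the difference.\n")

humans = generate_synthetic_trials(SyntheticDesign(n_participants=10, seed=12),
                                   [env])
hm = wv.measures_table(humans, env, fov=wv.HUMAN_FOV, n_rays=9,
                       visibility_stride=5)
diffs = wv.benchmark_differences(
    pd.concat(measures.values(), ignore_index=True), hm)
res = wv.agent_difference_lmer(diffs, "diff_time")
print("DifferenceInTime ~ AgentType + (1 | Agent):")
print(res.table.round(3).to_string())
print("\nA positive agent-type coefficient means the shortest-path agent "
      "deviates more from the human benchmark times than the visibility-"
      "based cognitive agent does.")
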