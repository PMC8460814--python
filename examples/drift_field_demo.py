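"""Isovists and the drift field that steers the cognitive agent.

Casts a 360-degree isovist at the entrance, then precomputes drift (distance
from each cell to its isovist centroid) for every navigation cell.  Low
drift marks the centres of open spaces, which is where the exploring agent
heads to gather more visual information.
"""

import numpy as np

import wayvis as wv

env = wv.build_building("centralized")
eye = np.array([env.entrance.x, env.entrance.y, 1.7])
iso = wv.compute_isovist(eye, env)
print(f"isovist at the entrance: area {iso.area:.1f} m^2, "
      f"drift {wv.isovist_drift(iso):.2f} m")

grid = wv.build_nav_grid(env, resolution=1.0)
field = wv.build_drift_field(grid, env)
for floor in (0, 1):
    vals = field.values[floor]
    i, j = np.unravel_index(np.nanargmin(vals), vals.shape)
    c = grid.cell_center((floor, int(i), int(j)))
    print(f"floor {floor + 1}: drift ranges "
          f"{np.nanmin(vals):.2f}-{np.nanmax(vals):.2f} m, "
          f"minimum at ({c[0]:.1f}, {c[1]:.1f})")
print("\nThe first-floor minimum sits at the centre of the open hall: an "
      "agent following minimal drift walks to where it can see the most.")
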