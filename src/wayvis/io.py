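"""File formats: trajectory CSV, environment JSON, drift rasters, run configs.

Trajectory CSV dialects
-----------------------
``native``
    Columns ``trial_id, subject_id, source, block, session, atria_type,
    destination_id, t, x, y, z, yaw, pitch``; z-up, metres, yaw in degrees
    CCW from +x, pitch positive up.  ``z`` is the camera (eye) height.
``unity``
    The same columns as logged by a Unity scene (y-up, left-handed).  The
    documented mapping to native is::

        x_native = x_unity        yaw_native   = 90 - yaw_unity  (wrapped)
        y_native = z_unity        pitch_native = -pitch_unity
        z_native = y_unity

    i.e. Unity's vertical axis becomes z, Unity yaw is measured clockwise
    from its +z (forward) axis, and Unity pitch is positive downward.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .building import (
    BuildingParams,
    Destination,
    Environment,
    Escalator,
    FloorPlan,
    Pose,
    RectOccluder,
    normalize_yaw,
)
from .trajectory import CSV_COLUMNS, Trajectory, frame_to_trajectories, trajectories_to_frame
from .visibility import DriftField


class SchemaError(ValueError):
    pass


def write_trajectories(trajs: list[Trajectory], path: str | Path) -> None:
    trajectories_to_frame(trajs).to_csv(path, index=False)


def read_trajectories(path: str | Path, dialect: str = "native") -> list[Trajectory]:
    """Read a trajectory CSV; ``dialect='unity'`` converts axes on the fly."""
    if dialect not in ("native", "unity"):
        raise ValueError("dialect must be 'native' or 'unity'")
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory file {path} is missing column(s): "
                          f"{', '.join(missing)}")
    if dialect == "unity":
        df = df.copy()
        y_up = df["y"].to_numpy().copy()
        df["y"] = df["z"]
        df["z"] = y_up
        df["yaw"] = [normalize_yaw(90.0 - v) for v in df["yaw"].to_numpy()]
        df["pitch"] = -df["pitch"]
    for trial, g in df.groupby("trial_id"):
        dt = np.diff(g["t"].to_numpy())
        if len(dt) and (dt <= 0).any():
            bad = int(np.nonzero(dt <= 0)[0][0]) + g.index[0] + 2  # header line
            raise SchemaError(
                f"non-monotone timestamps in trial {trial!r} near line {bad}")
    return frame_to_trajectories(df)


# ---------------------------------------------------------------------------
# Environment JSON
# ---------------------------------------------------------------------------

ENV_SCHEMA_VERSION = 1


def environment_to_dict(env: Environment) -> dict[str, Any]:
    return {
        "schema_version": ENV_SCHEMA_VERSION,
        "atria_type": env.atria_type,
        "params": dataclasses.asdict(env.params),
        "floors": [
            {
                "footprint": mapping(fl.footprint),
                "elevation": fl.elevation,
                "ceiling_height": fl.ceiling_height,
                "walkable": mapping(fl.walkable),
                "rooms": [mapping(r) for r in fl.rooms],
            }
            for fl in env.floors
        ],
        "occluders": [dataclasses.asdict(o) for o in env.occluders],
        "atria": [mapping(a) for a in env.atria],
        "destinations": [dataclasses.asdict(d) for d in env.destinations],
        "escalator": None if env.escalator is None else
        {"base": list(env.escalator.base), "top": list(env.escalator.top)},
        "entrance": dataclasses.asdict(env.entrance),
    }


def environment_from_dict(data: dict[str, Any],
                          allow_area_override: bool = False) -> Environment:
    for key in ("atria_type", "params", "floors", "occluders", "atria",
                "destinations", "entrance"):
        if key not in data:
            raise SchemaError(f"environment JSON missing key {key!r}")
    params = BuildingParams(**data["params"])
    floors = [
        FloorPlan(
            footprint=shape(f["footprint"]),
            elevation=float(f["elevation"]),
            ceiling_height=float(f["ceiling_height"]),
            walkable=shape(f["walkable"]),
            rooms=[shape(r) for r in f.get("rooms", [])],
        )
        for f in data["floors"]
    ]
    occluders = [
        RectOccluder(**{**o, "holes": tuple(tuple(h) for h in o.get("holes", ()))})
        for o in data["occluders"]
    ]
    atria = [shape(a) for a in data["atria"]]
    destinations = [Destination(**d) for d in data["destinations"]]
    esc = data.get("escalator")
    escalator = None if esc is None else Escalator(base=tuple(esc["base"]),
                                                  top=tuple(esc["top"]))
    env = Environment(
        atria_type=data["atria_type"], params=params, floors=floors,
        occluders=occluders, atria=atria, destinations=destinations,
        escalator=escalator, entrance=Pose(**data["entrance"]),
    )
    area = env.atria_area
    if not allow_area_override and abs(area - params.atria_total_area) \
            > 1e-6 * params.atria_total_area:
        raise SchemaError(
            f"atria area {area} m^2 does not match the declared total "
            f"{params.atria_total_area} m^2")
    return env


def save_environment(env: Environment, path: str | Path) -> None:
    Path(path).write_text(json.dumps(environment_to_dict(env), indent=1))


def load_environment(path: str | Path, **kw) -> Environment:
    return environment_from_dict(json.loads(Path(path).read_text()), **kw)


# ---------------------------------------------------------------------------
# Drift raster / isovist exports
# ---------------------------------------------------------------------------

def drift_field_to_ascii_grid(field: DriftField, floor: int,
                              nodata: float = -9999.0) -> str:
    """ESRI ASCII grid of one floor's drift raster (rows north to south)."""
    fg = field.grid.floors[floor]
    vals = np.where(np.isnan(field.values[floor]), nodata, field.values[floor])
    rows = [
        f"ncols {fg.nx}", f"nrows {fg.ny}",
        f"xllcorner {fg.origin[0]}", f"yllcorner {fg.origin[1]}",
        f"cellsize {field.grid.resolution}", f"NODATA_value {nodata}",
    ]
    for j in range(fg.ny - 1, -1, -1):
        rows.append(" ".join(f"{vals[i, j]:.6g}" for i in range(fg.nx)))
    return "\n".join(rows) + "\n"


def isovist_to_geojson(iso) -> dict[str, Any]:
    return {
        "type": "Feature",
        "geometry": mapping(iso.polygon),
        "properties": {"origin": list(map(float, iso.origin)),
                       "area": iso.area,
                       "drift": float(np.linalg.norm(iso.centroid - iso.origin[:2]))},
    }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Serializable description of one reproducible run."""

    atria_type: str = "centralized"
    environment_path: str | None = None
    grid_resolution: float = 1.0
    seed: int = 0
    n_samples: int = 100
    agent_type: str = "cognitive"
    arrival_radius: float = 0.5
    fov_horizontal: float = 91.0
    fov_vertical: float = 60.0
    view_range: float = 100.0
    n_rays: int = 100
    kde_bandwidth: str | float = "scott"
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.to_json())


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_json(Path(path).read_text())
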