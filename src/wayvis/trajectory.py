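"""Pose time-series container shared by human logs, agents, and fixtures.

A trajectory stores camera (eye) positions: ``z`` is the eye height above the
global ground plane, not the floor elevation.  Yaw/pitch follow the package
convention (degrees, yaw CCW from +x, pitch positive upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: canonical column order of the trajectory CSV dialect
CSV_COLUMNS = [
    "trial_id", "subject_id", "source", "block", "session", "atria_type",
    "destination_id", "t", "x", "y", "z", "yaw", "pitch",
]

SOURCES = ("human", "cognitive_agent", "shortest_path_agent", "synthetic")


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    trial_id: str = ""
    subject_id: str = ""
    source: str = "human"
    block: int = 1
    session: int = 1
    atria_type: str = "centralized"
    destination_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.t, self.x, self.y, self.z, self.yaw, self.pitch)]
        self.t, self.x, self.y, self.z, self.yaw, self.pitch = arrays
        n = len(self.t)
        if n < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if any(len(a) != n for a in arrays[1:]):
            raise ValueError("trajectory arrays must share one length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"timestamps must strictly increase (trial {self.trial_id!r})")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def slice(self, stop: int) -> "Trajectory":
        """Prefix containing samples [0, stop]."""
        return Trajectory(
            t=self.t[: stop + 1], x=self.x[: stop + 1], y=self.y[: stop + 1],
            z=self.z[: stop + 1], yaw=self.yaw[: stop + 1], pitch=self.pitch[: stop + 1],
            trial_id=self.trial_id, subject_id=self.subject_id, source=self.source,
            block=self.block, session=self.session, atria_type=self.atria_type,
            destination_id=self.destination_id, meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame({
            "trial_id": [self.trial_id] * n,
            "subject_id": [self.subject_id] * n,
            "source": [self.source] * n,
            "block": [self.block] * n,
            "session": [self.session] * n,
            "atria_type": [self.atria_type] * n,
            "destination_id": [self.destination_id] * n,
            "t": self.t, "x": self.x, "y": self.y, "z": self.z,
            "yaw": self.yaw, "pitch": self.pitch,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        first = df.iloc[0]
        return cls(
            t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
            z=df["z"].to_numpy(), yaw=df["yaw"].to_numpy(), pitch=df["pitch"].to_numpy(),
            trial_id=str(first["trial_id"]), subject_id=str(first["subject_id"]),
            source=str(first["source"]), block=int(first["block"]),
            session=int(first["session"]), atria_type=str(first["atria_type"]),
            destination_id=str(first["destination_id"]),
        )


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    return pd.concat([tr.to_frame() for tr in trajs], ignore_index=True)[CSV_COLUMNS]


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    return [Trajectory.from_frame(g.sort_values("t"))
            for _, g in df.groupby("trial_id", sort=False)]
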