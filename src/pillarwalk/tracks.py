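"""Per-cell centroid trajectories at the observation interval.

A :class:`Track` is one maximal contiguous run of observations of a cell
inside the visible window; times are re-zeroed to the first observation of
the run.  A :class:`TrackSet` bundles the tracks of one simulation or one
experiment and round-trips through the trajectory CSV format
(``cell_id,frame,t_seconds,x_um,y_um``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Track:
    cell_id: int
    t: np.ndarray  # seconds, re-zeroed to first observation
    x: np.ndarray  # um
    y: np.ndarray  # um

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise ValueError("tracks must contain at least one observation")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)
    dt_obs: float = 30.0  # seconds between consecutive observations

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def n_cells(self) -> int:
        return len(self.tracks)

    def lengths(self) -> np.ndarray:
        return np.array([len(tr) for tr in self.tracks], dtype=int)

    def max_length(self) -> int:
        return int(self.lengths().max()) if self.tracks else 0

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for k in range(len(tr)):
                rows.append((tr.cell_id, k, tr.t[k], tr.x[k], tr.y[k]))
        return pd.DataFrame(
            rows, columns=["cell_id", "frame", "t_seconds", "x_um", "y_um"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt_obs: float | None = None) -> "TrackSet":
        required = {"cell_id", "frame", "t_seconds", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trajectory table lacks columns {sorted(missing)}")
        tracks = []
        for cid, grp in df.groupby("cell_id", sort=True):
            grp = grp.sort_values("frame")
            t = grp["t_seconds"].to_numpy(dtype=float)
            tracks.append(
                Track(int(cid), t - t[0], grp["x_um"].to_numpy(), grp["y_um"].to_numpy())
            )
        if dt_obs is None:
            deltas = np.concatenate(
                [np.diff(tr.t) for tr in tracks if len(tr) > 1] or [np.array([30.0])]
            )
            dt_obs = float(np.median(deltas))
        return cls(tracks, dt_obs=dt_obs)

    @classmethod
    def from_csv(cls, path: str | Path, dt_obs: float | None = None) -> "TrackSet":
        return cls.from_dataframe(pd.read_csv(path), dt_obs=dt_obs)
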