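"""Observed-trajectory container and plain-text table I/O.

A Track holds the 2D localizations of one molecule: strictly increasing
frame indices where a difference of 2 records a single missing (gap)
position, positions in µm, and a per-localization uncertainty (posterior
std, µm).  Ground-truth state labels ride along when the track came from a
simulation so recovery can be scored.

Tables are plain columnar text (CSV) with one row per localization:
cell, track, frame, time_s, x_um, y_um, [z_um], loc_error_um, [state].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class Track:
    track_id: int
    cell_id: int
    frames: np.ndarray
    positions: np.ndarray  # (n, 2) µm
    loc_uncertainty: np.ndarray  # (n,) µm
    frame_dt: float = 0.02
    true_states: Optional[np.ndarray] = None
    true_z: Optional[np.ndarray] = None
    true_particle: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.loc_uncertainty = np.asarray(self.loc_uncertainty, dtype=float)
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must be (n_frames, 2)")
        d = np.diff(self.frames)
        if len(d) and (d.min() < 1 or d.max() > 2):
            raise ValueError("frame gaps must be exactly one missing frame")
        if len(self.frames) < 2:
            raise ValueError("track needs at least 2 localizations")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    @property
    def displacements(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    @property
    def dt_factors(self) -> np.ndarray:
        """1 for consecutive frames, 2 across a single-frame gap."""
        return np.diff(self.frames)

    @property
    def step_loc_var(self) -> np.ndarray:
        """Summed localization variance of each displacement's endpoints."""
        v = self.loc_uncertainty**2
        return v[:-1] + v[1:]


def total_steps(tracks: Sequence[Track]) -> int:
    return int(sum(t.n_steps for t in tracks))


def tracks_to_table(tracks: Iterable[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            row = {
                "cell": t.cell_id,
                "track": t.track_id,
                "frame": int(t.frames[i]),
                "time_s": t.frames[i] * t.frame_dt,
                "x_um": t.positions[i, 0],
                "y_um": t.positions[i, 1],
                "loc_error_um": t.loc_uncertainty[i],
            }
            if t.true_z is not None:
                row["z_um"] = t.true_z[i]
            if t.true_states is not None:
                row["state"] = int(t.true_states[i])
            rows.append(row)
    return pd.DataFrame(rows)


def tracks_from_table(df: pd.DataFrame, frame_dt: float | None = None) -> list[Track]:
    out: list[Track] = []
    for (cell, tid), g in df.groupby(["cell", "track"], sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            continue
        dt = frame_dt
        if dt is None:
            tt = g["time_s"].to_numpy()
            fr = g["frame"].to_numpy()
            dt = float((tt[-1] - tt[0]) / max(fr[-1] - fr[0], 1))
        out.append(
            Track(
                track_id=int(tid),
                cell_id=int(cell),
                frames=g["frame"].to_numpy(),
                positions=g[["x_um", "y_um"]].to_numpy(),
                loc_uncertainty=g["loc_error_um"].to_numpy(),
                frame_dt=dt,
                true_states=g["state"].to_numpy(dtype=int) if "state" in g else None,
                true_z=g["z_um"].to_numpy() if "z_um" in g else None,
            )
        )
    return out


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    tracks_to_table(tracks).to_csv(path, index=False)


def read_tracks(path: str | Path, frame_dt: float | None = None) -> list[Track]:
    return tracks_from_table(pd.read_csv(path), frame_dt=frame_dt)
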