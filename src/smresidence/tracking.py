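"""Frame-to-frame linking of localizations into trajectories.

Localizations in successive frames are connected if they lie within a
linking radius (default 400 nm) of each other.  Candidate links for each
frame pair are accepted greedily in ascending planar distance, each
localization participating in at most one link per side; ties at exactly
equal distance resolve by lowest row index.  There is no gap closing: a
missed detection terminates a track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .locio import LocalizationTable

__all__ = ["Trajectory", "link_trajectories", "trajectory_summary", "TrajectoryLinker"]


@dataclass
class Trajectory:
    """Frame-contiguous chain of localizations for one putative molecule."""

    id: int
    frames: np.ndarray  # strictly consecutive ints
    x: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None
    molecule_id: Optional[np.ndarray] = None  # ground truth, if present

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one localization")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("trajectory frames must be strictly consecutive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def duration(self, frame_interval: float) -> float:
        """Track duration (last frame − first frame) × frame interval, s."""
        return (self.frames[-1] - self.frames[0]) * frame_interval

    def steps(self) -> np.ndarray:
        """Planar displacements between consecutive frames, nm."""
        return np.hypot(np.diff(self.x), np.diff(self.y))


def _greedy_match(d: np.ndarray, max_link: float):
    """Greedy ascending-distance one-to-one matching on a distance matrix.

    Returns (i, j) index pairs; ties broken by lowest (i, j)."""
    ii, jj = np.nonzero(d <= max_link)
    if len(ii) == 0:
        return []
    dist = d[ii, jj]
    order = np.lexsort((jj, ii, dist))
    used_i = np.zeros(d.shape[0], dtype=bool)
    used_j = np.zeros(d.shape[1], dtype=bool)
    pairs = []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_i[i] and not used_j[j]:
            used_i[i] = used_j[j] = True
            pairs.append((i, j))
    return pairs


def link_trajectories(table: LocalizationTable, max_link_nm: float = 400.0) -> List[Trajectory]:
    """Link a localization table into trajectories.

    The table must be sorted by frame (tables from :mod:`smresidence.locio`
    are).  Every input localization is assigned to exactly one trajectory,
    so trajectory lengths sum to the number of localizations.
    """
    df = table.df
    if len(df) == 0:
        return []
    frames = df["frame"].to_numpy()
    x = df["x_nm"].to_numpy(dtype=float)
    y = df["y_nm"].to_numpy(dtype=float)
    has_z = "z_nm" in df.columns
    z = df["z_nm"].to_numpy(dtype=float) if has_z else None
    has_mid = "molecule_id" in df.columns
    mid = df["molecule_id"].to_numpy() if has_mid else None

    # row indices per frame, in table order (deterministic under same-frame
    # permutations because rows are sorted by (frame, x_nm))
    unique_frames, starts = np.unique(frames, return_index=True)
    bounds = list(starts) + [len(frames)]
    frame_rows = {f: np.arange(bounds[k], bounds[k + 1]) for k, f in enumerate(unique_frames)}

    track_of_row = np.full(len(df), -1, dtype=int)
    open_tracks: List[List[int]] = []  # row indices per track
    active: dict = {}  # row index at previous frame -> track index

    prev_frame = None
    for f in unique_frames:
        rows = frame_rows[f]
        new_active = {}
        if prev_frame is not None and f == prev_frame + 1 and len(active) > 0:
            prev_rows = np.fromiter(active.keys(), dtype=int)
            d = cdist(
                np.column_stack((x[prev_rows], y[prev_rows])),
                np.column_stack((x[rows], y[rows])),
            )
            for i, j in _greedy_match(d, max_link_nm):
                t = active[int(prev_rows[i])]
                r = int(rows[j])
                open_tracks[t].append(r)
                track_of_row[r] = t
                new_active[r] = t
        for r in rows:
            r = int(r)
            if track_of_row[r] == -1:
                open_tracks.append([r])
                t = len(open_tracks) - 1
                track_of_row[r] = t
                new_active[r] = t
        active = new_active
        prev_frame = f

    out = []
    for tid, rows in enumerate(open_tracks):
        rows = np.asarray(rows, dtype=int)
        out.append(
            Trajectory(
                id=tid,
                frames=frames[rows],
                x=x[rows],
                y=y[rows],
                z=z[rows] if has_z else None,
                molecule_id=mid[rows] if has_mid else None,
            )
        )
    return out


def trajectory_summary(trajs: List[Trajectory], frame_interval: float) -> pd.DataFrame:
    """Per-trajectory summary: length, duration and mean step size.

    Singleton trajectories have undefined mean step (NaN) and duration 0.
    """
    rows = []
    for t in trajs:
        steps = t.steps()
        rows.append(
            {
                "id": t.id,
                "n_frames": t.n_frames,
                "duration_s": t.duration(frame_interval),
                "mean_step_nm": float(np.mean(steps)) if len(steps) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["id", "n_frames", "duration_s", "mean_step_nm"])


def write_trajectories(trajs: List[Trajectory], path) -> None:
    """Serialize trajectories as delimited text (one row per localization)."""
    rows = []
    for t in trajs:
        for k in range(t.n_frames):
            row = {
                "trajectory_id": t.id,
                "frame": int(t.frames[k]),
                "x_nm": t.x[k],
                "y_nm": t.y[k],
            }
            if t.z is not None:
                row["z_nm"] = t.z[k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


class TrajectoryLinker(BaseEstimator):
    """Estimator form of :func:`link_trajectories`.

    Parameters
    ----------
    max_link_nm : float
        Maximum planar distance between localizations in successive
        frames for them to be connected (default 400 nm).
    """

    def __init__(self, max_link_nm: float = 400.0):
        self.max_link_nm = max_link_nm

    def fit(self, X: LocalizationTable, y=None):
        self.trajectories_ = link_trajectories(X, self.max_link_nm)
        self.n_trajectories_ = len(self.trajectories_)
        return self

    def transform(self, X: LocalizationTable) -> List[Trajectory]:
        return link_trajectories(X, self.max_link_nm)

    def fit_transform(self, X: LocalizationTable, y=None) -> List[Trajectory]:
        self.fit(X)
        return self.trajectories_
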