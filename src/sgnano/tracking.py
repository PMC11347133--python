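"""Trajectory linking of per-frame localizations.

Frame-to-frame nearest-neighbour linking with a hard displacement gate
(default 400 nm), no gap closing and no merge/split events, followed by a
minimum-length / minimum-duration filter. Candidate pairs between two
consecutive frames are linked greedily in ascending distance order, each
localization used at most once; a localization that finds no partner starts
(or ends) a track.

Coordinates are in nanometres throughout; time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class Track:
    """One molecule's trajectory: consecutive frames, positions in nm."""

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    frame_time: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames must be (n,), xy must be (n, 2)")
        if self.frames.size == 0:
            raise ValueError("empty track")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be consecutive (no gaps)")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")

    @property
    def n_points(self) -> int:
        return self.frames.size

    @property
    def duration(self) -> float:
        """Track duration in s, counting each point as one frame of record."""
        return self.n_points * self.frame_time

    def displacements(self) -> np.ndarray:
        """Per-step Euclidean displacements in nm."""
        return np.hypot(*np.diff(self.xy, axis=0).T)


@dataclass
class TrackSet:
    """A collection of tracks plus the parameters that produced it."""

    tracks: list[Track]
    frame_time: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (t.track_id, f, x, y)
            for t in self.tracks
            for f, (x, y) in zip(t.frames, t.xy)
        ]
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_time: float) -> "TrackSet":
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            tracks.append(
                Track(int(tid), grp["frame"].to_numpy(), grp[["x", "y"]].to_numpy(), frame_time)
            )
        return cls(tracks, frame_time)


def link(locs: pd.DataFrame, max_disp: float = 400.0, frame_time: float = 0.018) -> TrackSet:
    """Link a localization table into trajectories.

    Parameters
    ----------
    locs
        DataFrame with at least ``frame``, ``x``, ``y`` columns (nm).
    max_disp
        Hard gate on the travel distance between consecutive frames (nm).
    frame_time
        Frame interval in seconds, stored on the resulting tracks.

    Localizations are first put into a canonical order (frame, x, y) so the
    track partition is independent of input row order; equidistant candidate
    pairs are broken by this canonical point index.
    """
    if not {"frame", "x", "y"}.issubset(locs.columns):
        raise ValueError("locs must have frame, x, y columns")
    df = locs.sort_values(["frame", "x", "y"], kind="mergesort").reset_index(drop=True)
    frames = df["frame"].to_numpy(dtype=int)
    xy = df[["x", "y"]].to_numpy(dtype=float)

    open_tracks: dict[int, list[int]] = {}  # row index of last point -> list of row indices
    finished: list[list[int]] = []

    unique_frames = np.unique(frames)
    # rows per frame
    rows_by_frame = {f: np.flatnonzero(frames == f) for f in unique_frames}

    prev_frame = None
    active: dict[int, list[int]] = {}  # keyed by last row index
    for f in unique_frames:
        rows = rows_by_frame[f]
        if prev_frame is not None and f == prev_frame + 1 and active:
            last_rows = np.fromiter(active.keys(), dtype=int)
            tree_b = cKDTree(xy[rows])
            pairs = []  # (distance, a_pos, b_pos)
            for a_pos, ar in enumerate(last_rows):
                for b_pos in tree_b.query_ball_point(xy[ar], max_disp):
                    d = float(np.hypot(*(xy[rows[b_pos]] - xy[ar])))
                    pairs.append((d, a_pos, b_pos))
            pairs.sort()
            used_a: set[int] = set()
            used_b: set[int] = set()
            for d, a_pos, b_pos in pairs:
                if a_pos in used_a or b_pos in used_b:
                    continue
                used_a.add(a_pos)
                used_b.add(b_pos)
                ar, br = int(last_rows[a_pos]), int(rows[b_pos])
                track_rows = active.pop(ar)
                track_rows.append(br)
                active[br] = track_rows
            # unmatched previous-frame tracks are closed
            for a_pos, ar in enumerate(last_rows):
                if a_pos not in used_a and int(ar) in active:
                    finished.append(active.pop(int(ar)))
            # unmatched current-frame points start new tracks
            for b_pos, br in enumerate(rows):
                if b_pos not in used_b:
                    active[int(br)] = [int(br)]
        else:
            # a frame gap (or the first frame) closes everything open
            finished.extend(active.values())
            active = {}
            for br in rows:
                active[int(br)] = [int(br)]
        prev_frame = f
    finished.extend(active.values())

    tracks = []
    for tid, rows_list in enumerate(sorted(finished, key=lambda r: (frames[r[0]], r[0]))):
        idx = np.asarray(rows_list, dtype=int)
        tracks.append(Track(tid, frames[idx], xy[idx], frame_time))
    return TrackSet(
        tracks,
        frame_time,
        provenance={"max_disp_nm": max_disp, "n_localizations": len(df)},
    )


def filter_tracks(ts: TrackSet, min_points: int = 40, min_duration: float = 0.720) -> TrackSet:
    """Keep tracks with ≥ ``min_points`` points and duration ≥ ``min_duration``.

    Duration counts every point as one frame of record (n·Δt), so a 40-point
    track at 18 ms (720 ms of record) passes the default filter and a
    39-point track does not. Both criteria are applied; the boundary is
    inclusive.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    kept = [
        t for t in ts
        if t.n_points >= min_points and t.duration >= min_duration - 1e-12
    ]
    prov = dict(ts.provenance)
    prov.update({"min_points": min_points, "min_duration_s": min_duration})
    return TrackSet(kept, ts.frame_time, prov)
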