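"""Dot identity tracking by centroid proximity across frames.

Each detected dot is linked to the nearest active track whose last known
centroid lies within a distance threshold, mirroring tracking by comparing
each centroid to the dots of previous frames and assigning persistent IDs by
proximity.  Bursting nuclei blink off for many frames, so tracks tolerate
off-gaps up to ``max_gap_frames`` before being closed; set it to 0 for strict
previous-frame linking.

Tracking is restarted for every nuclear-cycle stage (mitosis scrambles
identities anyway); track IDs are per-stage, assigned in creation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import DotObservation


@dataclass
class TrackingParams:
    max_link_dist_px: float = 15.0
    max_gap_frames: int = 10
    assignment: str = "greedy"   # or "optimal" (min-total-distance per frame)

    def __post_init__(self) -> None:
        if self.max_link_dist_px <= 0:
            raise ValueError("max_link_dist_px must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.assignment not in ("greedy", "optimal"):
            raise ValueError("assignment must be 'greedy' or 'optimal'")


@dataclass
class Track:
    """Frame-ordered observations sharing one identity, with run structure.

    ``on_runs`` are maximal intervals (start, end inclusive) of consecutive
    frames in which the dot is present; ``off_gaps`` the gaps between them.
    Together they tile the span [first_frame, last_frame] exactly.
    """

    track_id: int
    observations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [o.frame for o in self.observations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("observation frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([o.frame for o in self.observations], dtype=int)

    @property
    def first_frame(self) -> int:
        return self.observations[0].frame

    @property
    def last_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def on_runs(self) -> list:
        runs = []
        for f in self.frames:
            if runs and f == runs[-1][1] + 1:
                runs[-1][1] = f
            else:
                runs.append([f, f])
        return [tuple(r) for r in runs]

    @property
    def off_gaps(self) -> list:
        runs = self.on_runs
        return [(a[1] + 1, b[0] - 1) for a, b in zip(runs, runs[1:])]


def link_frames(dots_by_frame: list, params: TrackingParams | None = None) -> list:
    """Link per-frame dot lists into tracks by nearest-centroid assignment.

    Frame by frame, each dot is matched to at most one active track whose last
    centroid (seen within ``max_gap_frames``) lies within ``max_link_dist_px``.
    ``greedy`` matches candidate pairs in ascending distance order (ties broken
    by lower track ID, then detection order); ``optimal`` solves the
    minimum-total-distance assignment per frame.  Unmatched dots open new
    tracks with fresh sequential IDs; each dot's ``track_id`` is filled in.
    """
    params = params or TrackingParams()
    obs_lists: list[list] = []   # obs_lists[tid] = observations of track tid
    active: list[int] = []       # track ids still eligible for linking

    for frame_idx, dots in enumerate(dots_by_frame):
        active = [ti for ti in active
                  if frame_idx - obs_lists[ti][-1].frame - 1 <= params.max_gap_frames]
        if dots:
            pairs = _match(dots, [obs_lists[ti][-1].centroid for ti in active], params)
            matched_dots = {d for d, _ in pairs}
            for d_i, a_i in pairs:
                ti = active[a_i]
                obs_lists[ti].append(replace(dots[d_i], frame=frame_idx, track_id=ti))
            for d_i, dot in enumerate(dots):
                if d_i not in matched_dots:
                    tid = len(obs_lists)
                    obs_lists.append([replace(dot, frame=frame_idx, track_id=tid)])
                    active.append(tid)

    return [Track(track_id=tid, observations=obs)
            for tid, obs in enumerate(obs_lists)]


def _match(dots, last_centroids, params: TrackingParams) -> list:
    """Return (dot_index, active_index) pairs within the link distance."""
    if not last_centroids:
        return []
    d = np.array([dot.centroid for dot in dots], dtype=float)
    c = np.array(last_centroids, dtype=float)
    dist = np.sqrt(((d[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    in_range = dist <= params.max_link_dist_px

    if params.assignment == "optimal":
        big = params.max_link_dist_px * 1e6
        cost = np.where(in_range, dist, big)
        rows, cols = linear_sum_assignment(cost)
        return [(int(r), int(c_)) for r, c_ in zip(rows, cols) if in_range[r, c_]]

    # greedy: ascending distance; ties by lower track index, then dot order
    cand = [(dist[i, j], j, i) for i in range(len(dots))
            for j in range(len(last_centroids)) if in_range[i, j]]
    cand.sort()
    pairs, used_d, used_t = [], set(), set()
    for _, j, i in cand:
        if i in used_d or j in used_t:
            continue
        pairs.append((i, j))
        used_d.add(i)
        used_t.add(j)
    return pairs


def tracks_to_table(tracks: list) -> pd.DataFrame:
    """Long-form table of all track observations (lossless inverse of grouping)."""
    rows = [{
        "track_id": t.track_id,
        "frame": o.frame,
        "row": o.centroid[0],
        "col": o.centroid[1],
        "area_px": o.area_px,
        "mean_brightness": o.mean_brightness,
        "norm_brightness": o.norm_brightness,
        "stage": o.stage_label,
    } for t in tracks for o in t.observations]
    return pd.DataFrame(rows, columns=["track_id", "frame", "row", "col", "area_px",
                                       "mean_brightness", "norm_brightness", "stage"])


def table_to_tracks(table: pd.DataFrame) -> list:
    """Rebuild Track objects from a long-form table written by tracks_to_table."""
    tracks = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        obs = [DotObservation(
            frame=int(r.frame), centroid=(float(r.row), float(r.col)),
            area_px=int(r.area_px), mean_brightness=float(r.mean_brightness),
            norm_brightness=None if pd.isna(r.norm_brightness) else float(r.norm_brightness),
            stage_label=None if pd.isna(r.stage) else r.stage,
            track_id=int(tid),
        ) for r in grp.itertuples()]
        tracks.append(Track(track_id=int(tid), observations=obs))
    return tracks
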