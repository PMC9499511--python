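"""Trajectory building: frame-to-frame assignment with single-frame gaps.

Detections in consecutive frames are matched by minimum total squared
displacement (optimal bipartite assignment per frame pair) with a hard
maximum step; a track that missed one frame may reconnect in the next at
doubled cost, recording one missing position.  Per cell, track building
starts at the first frame from which at most N spots remain in that cell in
every following frame (N = 1 by default, 2 for membrane-marker movies) —
this avoids ambiguous multi-spot episodes at movie start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import Detection
from .tracks import Track


def start_rule_filter(
    counts_per_frame: Sequence[int], max_spots: int = 1
) -> Optional[int]:
    """Earliest frame index t such that every frame >= t has <= max_spots
    detections; None if no such frame exists (cell excluded)."""
    counts = np.asarray(list(counts_per_frame), dtype=int)
    ok = counts <= max_spots
    # last False, then everything after is usable
    bad = np.flatnonzero(~ok)
    if len(bad) == 0:
        return 0
    t = int(bad[-1]) + 1
    return t if t < len(counts) else None


@dataclass
class _Open:
    detections: list
    last_frame: int


def link_tracks(
    detections: Sequence[Detection],
    max_step: float,
    gap: int = 1,
    start_rule_n: int = 1,
    frame_dt: float = 0.02,
    min_length: int = 2,
) -> list[Track]:
    """Link detections (one cell's worth, or with cell ids set) into tracks.

    Assignment per frame pair minimizes summed squared displacement; births
    and deaths are free beyond ``max_step``.  A track unmatched in one frame
    stays eligible for the next frame at doubled cost (single-frame gap
    closing) if ``gap`` >= 1.
    """
    by_cell: dict[int, list[Detection]] = {}
    for d in detections:
        by_cell.setdefault(d.cell_id, []).append(d)
    tracks: list[Track] = []
    tid = 0
    for cell_id in sorted(by_cell):
        dets = sorted(by_cell[cell_id], key=lambda d: d.frame)
        frames: dict[int, list[Detection]] = {}
        for d in dets:
            frames.setdefault(d.frame, []).append(d)
        if not frames:
            continue
        f_lo, f_hi = min(frames), max(frames)
        counts = [len(frames.get(f, [])) for f in range(f_lo, f_hi + 1)]
        t0 = start_rule_filter(counts, max_spots=start_rule_n)
        if t0 is None:
            continue  # cell excluded: never settles to <= N spots
        open_tracks: list[_Open] = []
        closed: list[list[Detection]] = []
        for f in range(f_lo + t0, f_hi + 1):
            ds = frames.get(f, [])
            # candidate open tracks: last seen at f-1, or f-2 (gap)
            cands = [o for o in open_tracks if f - o.last_frame <= gap + 1]
            expired = [o for o in open_tracks if f - o.last_frame > gap + 1]
            closed.extend(o.detections for o in expired)
            if not ds:
                open_tracks = cands
                continue
            n_t, n_d = len(cands), len(ds)
            if n_t:
                big = 1e12
                cost = np.full((n_t + n_d, n_d + n_t), big)
                for i, o in enumerate(cands):
                    last = o.detections[-1]
                    dt_frames = f - o.last_frame
                    for j, d in enumerate(ds):
                        c = (d.x - last.x) ** 2 + (d.y - last.y) ** 2
                        if dt_frames > 1:
                            c *= 2.0  # gap closing at doubled cost
                        if c <= dt_frames * max_step**2:
                            cost[i, j] = c
                birth_death = max_step**2
                for i in range(n_t):
                    cost[i, n_d + i] = birth_death  # track death
                for j in range(n_d):
                    cost[n_t + j, j] = birth_death  # detection birth
                cost[n_t:, n_d:] = 0.0
                rows, cols = linear_sum_assignment(cost)
                matched_d = set()
                still_open: list[_Open] = []
                for i, j in zip(rows, cols):
                    if i < n_t and j < n_d and cost[i, j] < big:
                        cands[i].detections.append(ds[j])
                        cands[i].last_frame = f
                        matched_d.add(j)
                        still_open.append(cands[i])
                    elif i < n_t:
                        still_open.append(cands[i])  # unmatched; may gap-close
                for j, d in enumerate(ds):
                    if j not in matched_d:
                        still_open.append(_Open([d], f))
                open_tracks = still_open
            else:
                open_tracks = [_Open([d], f) for d in ds]
        closed.extend(o.detections for o in open_tracks)
        for det_list in closed:
            if len(det_list) < min_length:
                continue
            frames_arr = np.array([d.frame for d in det_list])
            tracks.append(
                Track(
                    track_id=tid,
                    cell_id=cell_id,
                    frames=frames_arr,
                    positions=np.array([[d.x, d.y] for d in det_list]),
                    loc_uncertainty=np.array([d.loc_uncertainty for d in det_list]),
                    frame_dt=frame_dt,
                )
            )
            tid += 1
    return tracks
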