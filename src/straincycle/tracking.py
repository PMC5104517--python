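"""Single-cell tracking: frame-to-frame linking, gap closing, division calls.

Linking is optimal bipartite assignment on squared centroid displacement with
a hard distance gate (pairs beyond the gate are forbidden and fall out as
appearances/disappearances).  Tracks are chained from the per-frame
assignments; short detection dropouts are bridged by gap closing.  A division
is called geometrically: a track that terminates with at least two new tracks
appearing close to its terminal position within a short window is marked as a
parent and the two nearest candidates become daughters.  Fluorescence
confirmation of divisions lives in :mod:`straincycle.events`.

All distances are physical (um); positions enter as pixel centroids times the
pixel size, or directly in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .params import TrackingParams

__all__ = ["Track", "link_frames", "build_tracks", "annotate_divisions", "track_table"]


@dataclass
class Track:
    """A time-ordered chain of detections belonging to one cell."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)  # um
    labels: list[int] = field(default_factory=list)
    parent_track_id: Optional[int] = None
    daughter_track_ids: Optional[tuple[int, int]] = None

    @property
    def appearance_frame(self) -> int:
        return self.frames[0]

    @property
    def disappearance_frame(self) -> int:
        return self.frames[-1]

    def terminal_position(self) -> tuple[float, float]:
        return self.positions[-1]


def link_frames(
    points_a: Sequence[tuple[float, float]],
    points_b: Sequence[tuple[float, float]],
    max_displacement_um: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimal one-to-one assignment between consecutive frames.

    Minimizes total squared displacement subject to a hard gate: no link may
    be longer than ``max_displacement_um``.  Returns ``(matches,
    unmatched_a, unmatched_b)`` where matches are index pairs into the two
    point lists.  Implemented with the standard augmented (dummy-padded)
    rectangular assignment so that leaving a point unmatched costs exactly
    the gate; this is equivalent to exhaustive minimum-cost matching.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return [], list(range(na)), list(range(nb))
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    gate2 = max_displacement_um**2
    big = 1e12
    cost = np.full((na + nb, nb + na), big)
    linkable = d2 <= gate2
    cost[:na, :nb] = np.where(linkable, d2, big)
    cost[:na, nb:][np.eye(na, dtype=bool)] = gate2  # a_i -> unmatched
    cost[na:, :nb][np.eye(nb, dtype=bool)] = gate2  # unmatched -> b_j
    cost[na:, nb:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    matches = []
    matched_a, matched_b = set(), set()
    for i, j in zip(rows, cols):
        if i < na and j < nb and linkable[i, j]:
            matches.append((int(i), int(j)))
            matched_a.add(i)
            matched_b.add(j)
    unmatched_a = [i for i in range(na) if i not in matched_a]
    unmatched_b = [j for j in range(nb) if j not in matched_b]
    return matches, unmatched_a, unmatched_b


def build_tracks(
    nuclei: pd.DataFrame,
    params: TrackingParams | None = None,
) -> list[Track]:
    """Link a nucleus table into tracks, with gap closing.

    ``nuclei`` must have columns ``frame, label, x_um, y_um`` (one row per
    detection).  A track end followed within ``max_gap_frames`` by a track
    start inside the (per-missing-frame scaled) gate is bridged into a single
    track.  Track ids are assigned in order of appearance.
    """
    params = params or TrackingParams()
    if len(nuclei) == 0:
        return []
    # contiguous frame range: a frame with no detections still advances time
    frames = list(range(int(nuclei["frame"].min()), int(nuclei["frame"].max()) + 1))
    grouped = dict(tuple(nuclei.groupby("frame")))
    empty = nuclei.iloc[0:0]
    by_frame = {
        f: grouped.get(f, empty).reset_index(drop=True) for f in frames
    }

    tracks: list[Track] = []
    # open_tracks maps detection index in the current frame -> track
    open_tracks: dict[int, Track] = {}

    def start_track(frame: int, row) -> Track:
        t = Track(track_id=len(tracks))
        t.frames.append(int(frame))
        t.positions.append((float(row.x_um), float(row.y_um)))
        t.labels.append(int(row.label))
        tracks.append(t)
        return t

    prev_frame = None
    for f in frames:
        cur = by_frame[f]
        if prev_frame is None:
            open_tracks = {
                i: start_track(f, row) for i, row in enumerate(cur.itertuples())
            }
        else:
            prev = by_frame[prev_frame]
            pts_a = list(zip(prev["x_um"], prev["y_um"]))
            pts_b = list(zip(cur["x_um"], cur["y_um"]))
            matches, _, unmatched_b = link_frames(
                pts_a, pts_b, params.max_displacement_um
            )
            new_open: dict[int, Track] = {}
            for i, j in matches:
                t = open_tracks.get(i)
                if t is None:
                    continue
                row = cur.iloc[j]
                t.frames.append(int(f))
                t.positions.append((float(row["x_um"]), float(row["y_um"])))
                t.labels.append(int(row["label"]))
                new_open[j] = t
            for j in unmatched_b:
                row = cur.iloc[j]
                t = Track(track_id=len(tracks))
                t.frames.append(int(f))
                t.positions.append((float(row["x_um"]), float(row["y_um"])))
                t.labels.append(int(row["label"]))
                tracks.append(t)
                new_open[j] = t
            open_tracks = new_open
        prev_frame = f

    if params.max_gap_frames > 0:
        _close_gaps(tracks, params)
    return tracks


def _close_gaps(tracks: list[Track], params: TrackingParams) -> None:
    """Bridge (end, start) pairs separated by <= max_gap missing frames."""
    ends = {t.track_id: t for t in tracks}
    candidates = []
    for t_end in tracks:
        for t_start in tracks:
            if t_start.track_id == t_end.track_id:
                continue
            gap = t_start.appearance_frame - t_end.disappearance_frame - 1
            if not (1 <= gap <= params.max_gap_frames):
                continue
            ex, ey = t_end.terminal_position()
            sx, sy = t_start.positions[0]
            dist = float(np.hypot(sx - ex, sy - ey))
            if dist <= params.max_displacement_um * (gap + 1):
                candidates.append((gap, dist, t_end.track_id, t_start.track_id))
    candidates.sort()
    used_ends, used_starts = set(), set()
    merges = []
    for gap, dist, eid, sid in candidates:
        if eid in used_ends or sid in used_starts:
            continue
        used_ends.add(eid)
        used_starts.add(sid)
        merges.append((eid, sid))
    # apply merges transitively (a bridged track may itself be bridged)
    absorbed = {}
    for eid, sid in merges:
        target = ends[eid]
        while target.track_id in absorbed:
            target = absorbed[target.track_id]
        source = ends[sid]
        target.frames.extend(source.frames)
        target.positions.extend(source.positions)
        target.labels.extend(source.labels)
        absorbed[sid] = target
    tracks[:] = [t for t in tracks if t.track_id not in absorbed]
    for new_id, t in enumerate(tracks):
        t.track_id = new_id


def annotate_divisions(
    tracks: list[Track],
    params: TrackingParams | None = None,
    last_frame: int | None = None,
) -> list[Track]:
    """Mark geometric track splits as candidate divisions (in place).

    A track terminating at frame f becomes a parent if at least two new
    tracks appear within ``split_radius_um`` of its terminal position in
    frames (f, f + split_window].  The two candidates with the smallest
    summed distance become daughters; ties break towards lower track ids.
    Tracks reaching the end of the movie are never parents.
    """
    params = params or TrackingParams()
    if last_frame is None:
        last_frame = max((t.disappearance_frame for t in tracks), default=0)
    starts_by_frame: dict[int, list[Track]] = {}
    for t in tracks:
        starts_by_frame.setdefault(t.appearance_frame, []).append(t)
    claimed: set[int] = set()
    for parent in sorted(tracks, key=lambda t: (t.disappearance_frame, t.track_id)):
        f = parent.disappearance_frame
        if f >= last_frame:
            continue
        px, py = parent.terminal_position()
        cands = []
        for g in range(f + 1, f + params.split_window_frames + 1):
            for t in starts_by_frame.get(g, []):
                if t.track_id == parent.track_id or t.track_id in claimed:
                    continue
                sx, sy = t.positions[0]
                d = float(np.hypot(sx - px, sy - py))
                if d <= params.split_radius_um:
                    cands.append((d, t.track_id, t))
        if len(cands) < 2:
            continue
        cands.sort(key=lambda c: (c[0], c[1]))
        best = None
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                key = (
                    cands[i][0] + cands[j][0],
                    min(cands[i][1], cands[j][1]),
                    max(cands[i][1], cands[j][1]),
                )
                if best is None or key < best[0]:
                    best = (key, cands[i][2], cands[j][2])
        _, d1, d2 = best
        parent.daughter_track_ids = (d1.track_id, d2.track_id)
        d1.parent_track_id = parent.track_id
        d2.parent_track_id = parent.track_id
        claimed.update({d1.track_id, d2.track_id})
    return tracks


def track_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table (track_id, frame, label, x_um, y_um)."""
    rows = []
    for t in tracks:
        for f, (x, y), lab in zip(t.frames, t.positions, t.labels):
            rows.append((t.track_id, f, lab, x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "label", "x_um", "y_um"])
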