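"""Fucci trace classification and cell-cycle event accounting.

A Fucci cell is red (mKO2-Cdt1) in G0/G1 and green (mAG-Geminin) from S entry
until mitosis, so the red -> green -> red sequence of a track reads out
G1 -> S -> division.  Frames are called GREEN/RED with hysteresis on the
balance ratio green/(green+red): a trace turns GREEN when the ratio rises
above ``on_ratio`` and only reverts below ``off_ratio``.  A mitosis is
confirmed when a GREEN trace terminates on an annotated track split (lineage
evidence) -- fluorescence collapse or a split alone is logged as a warning.

Event counts follow the movie-frame accounting convention: occurrences per
0.43 mm^2 frame, also normalized per 0.1 mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import EventParams
from .tracking import Track

__all__ = [
    "PhaseTrace",
    "EventCounts",
    "classify_trace",
    "geminin_fraction_series",
    "count_cycle_events",
]

logger = logging.getLogger(__name__)

RED, GREEN, UNKNOWN = "RED", "GREEN", "UNKNOWN"


@dataclass
class PhaseTrace:
    track_id: int
    frames: list[int]
    calls: list[str]
    s_entry_frame: Optional[int] = None
    mitosis_frame: Optional[int] = None
    sg2_dwell_frames: Optional[int] = None
    has_daughters: bool = False

    def sg2_dwell_hours(self, frame_interval_h: float) -> Optional[float]:
        if self.sg2_dwell_frames is None:
            return None
        return self.sg2_dwell_frames * frame_interval_h


def classify_trace(
    track: Track,
    red_series: np.ndarray,
    green_series: np.ndarray,
    on_threshold: float = 0.6,
    off_threshold: float = 0.4,
) -> PhaseTrace:
    """Classify one track's fluorescence trace into RED/GREEN phases.

    ``red_series``/``green_series`` are background-subtracted mean nuclear
    intensities per frame of the track.  ``s_entry_frame`` is the first GREEN
    call; ``mitosis_frame`` is set when the trace ends GREEN on a track with
    annotated daughters, or collapses GREEN -> RED within the track.  The
    S/G2 dwell is the span from S entry to mitosis (or track end for cells
    still green when the movie ends).
    """
    if not on_threshold > off_threshold:
        raise ValueError(
            f"hysteresis requires on_threshold > off_threshold, got "
            f"{on_threshold} <= {off_threshold}"
        )
    red = np.clip(np.asarray(red_series, dtype=float), 0.0, None)
    green = np.clip(np.asarray(green_series, dtype=float), 0.0, None)
    total = red + green
    calls: list[str] = []
    state = RED
    for r, g, tot in zip(red, green, total):
        if tot <= 0:
            calls.append(UNKNOWN)
            continue
        ratio = g / tot
        if state == RED and ratio > on_threshold:
            state = GREEN
        elif state == GREEN and ratio < off_threshold:
            state = RED
        calls.append(state)

    trace = PhaseTrace(
        track_id=track.track_id,
        frames=list(track.frames),
        calls=calls,
        has_daughters=track.daughter_track_ids is not None,
    )
    green_idx = [i for i, c in enumerate(calls) if c == GREEN]
    if green_idx:
        first = green_idx[0]
        trace.s_entry_frame = track.frames[first]
        # one RED->GREEN and at most one GREEN->RED transition are considered
        after = calls[first:]
        collapse = next((k for k, c in enumerate(after) if c == RED), None)
        if collapse is not None:
            trace.mitosis_frame = track.frames[first + collapse - 1]
        elif trace.has_daughters and after[-1] == GREEN:
            trace.mitosis_frame = track.frames[-1]
        end = trace.mitosis_frame if trace.mitosis_frame is not None else track.frames[-1]
        trace.sg2_dwell_frames = end - trace.s_entry_frame
    return trace


def geminin_fraction_series(
    nuclei: pd.DataFrame, green_threshold: float, green_column: str = "mean_green"
) -> pd.Series:
    """Percent Geminin-positive nuclei per frame.

    Equivalent to thresholding each frame's records with a constant
    threshold.  Frames with no nuclei yield NaN (flagged missing, not zero).
    """
    def pct(group: pd.Series) -> float:
        values = group.dropna()
        if len(values) == 0:
            return np.nan
        return 100.0 * float((values > green_threshold).sum()) / len(values)

    series = nuclei.groupby("frame")[green_column].apply(pct)
    if len(series):
        full = range(int(series.index.min()), int(series.index.max()) + 1)
        series = series.reindex(full)
    return series


@dataclass
class EventCounts:
    """Cycle-event tallies of one movie."""

    bins: pd.DataFrame  # bin_start_h, s_entries, mitoses, mitoses_per_h_per_frame, mitoses_per_h_per_0p1mm2
    accumulated: int  # tracks that went red -> green (entered S/G2)
    divided: int  # tracks that went red -> green -> divided
    frame_area_mm2: float
    total_hours: float

    @property
    def mitoses_per_h_per_0p1mm2(self) -> float:
        if self.total_hours <= 0:
            return 0.0
        return self.divided / self.total_hours / (self.frame_area_mm2 / 0.1)


def count_cycle_events(
    traces: list[PhaseTrace],
    frame_interval_h: float,
    n_frames: int,
    frame_area_mm2: float = 0.43,
    bin_hours: float = 1.0,
) -> EventCounts:
    """Tally S entries and confirmed mitoses into time bins.

    A mitosis requires both lines of evidence -- a GREEN trace and an
    annotated lineage split; traces with only one are logged as warnings.  A
    GREEN trace that reaches the end of the movie without dividing counts as
    "accumulated" only; ``divided <= accumulated`` always holds.
    """
    total_hours = max((n_frames - 1) * frame_interval_h, 0.0)
    n_bins = max(int(np.ceil(total_hours / bin_hours)), 1)
    edges = np.arange(n_bins + 1) * bin_hours
    s_counts = np.zeros(n_bins, dtype=int)
    m_counts = np.zeros(n_bins, dtype=int)
    accumulated = 0
    divided = 0
    for tr in traces:
        went_green = tr.s_entry_frame is not None
        if went_green:
            accumulated += 1
            t = tr.s_entry_frame * frame_interval_h
            s_counts[min(int(t // bin_hours), n_bins - 1)] += 1
        if tr.mitosis_frame is not None and tr.has_daughters and went_green:
            divided += 1
            t = tr.mitosis_frame * frame_interval_h
            m_counts[min(int(t // bin_hours), n_bins - 1)] += 1
        elif tr.mitosis_frame is not None and not tr.has_daughters:
            logger.warning(
                "track %d: green collapse without a lineage split (not counted)",
                tr.track_id,
            )
        elif tr.has_daughters and not went_green:
            logger.warning(
                "track %d: lineage split without a green segment (not counted)",
                tr.track_id,
            )
    bins = pd.DataFrame(
        {
            "bin_start_h": edges[:-1],
            "s_entries": s_counts,
            "mitoses": m_counts,
        }
    )
    bins["mitoses_per_h_per_frame"] = bins["mitoses"] / bin_hours
    bins["mitoses_per_h_per_0p1mm2"] = bins["mitoses_per_h_per_frame"] / (
        frame_area_mm2 / 0.1
    )
    return EventCounts(
        bins=bins,
        accumulated=accumulated,
        divided=divided,
        frame_area_mm2=frame_area_mm2,
        total_hours=total_hours,
    )
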