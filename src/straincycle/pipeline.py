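"""End-to-end quantification: stack -> nuclei -> tracks -> traces -> counts.

These helpers wire the per-module operations into the movie-level analysis:
segment every frame of a rendered stack, quantify channel intensities per
nucleus, link nuclei into tracks with division annotation, classify the Fucci
traces, and tally cycle events.  They are what the command-line interface and
the acceptance recomputations run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventCounts, PhaseTrace, classify_trace, count_cycle_events, geminin_fraction_series
from .imaging import ImageStack
from .params import EventParams, SegmentationParams, TrackingParams
from .segment import measure_nuclei, segment_nuclei
from .tracking import Track, annotate_divisions, build_tracks

__all__ = [
    "quantify_stack",
    "track_nuclei",
    "classify_tracks",
    "MovieAnalysis",
    "analyze_stack",
]


def quantify_stack(
    stack: ImageStack,
    seg_params: SegmentationParams | None = None,
    channels: tuple[str, ...] | None = None,
    return_labels: bool = False,
):
    """Segment and measure every frame of a stack.

    Returns a tidy nucleus table with columns ``frame, label, x_px, y_px,
    x_um, y_um, area_px2, mean_<channel>...`` plus per-frame background
    medians ``bg_<channel>`` (the median is a robust background estimate when
    nuclei cover a small fraction of the frame).
    """
    seg_params = seg_params or SegmentationParams()
    channels = channels or stack.channels
    nuclear_idx = list(stack.channels).index("nuclear")
    px = stack.pixel_size_um
    rows = []
    label_stack = []
    for f in range(stack.n_frames):
        frame = stack.data[f]
        labels, records = segment_nuclei(frame[nuclear_idx], seg_params)
        if return_labels:
            label_stack.append(labels)
        channel_images = {
            name: frame[list(stack.channels).index(name)] for name in channels
        }
        measure_nuclei(labels, channel_images, records=records, frame=f)
        bg = {name: float(np.median(img)) for name, img in channel_images.items()}
        for r in records:
            row = {
                "frame": f,
                "label": r.label,
                "x_px": r.x,
                "y_px": r.y,
                "x_um": r.x * px,
                "y_um": r.y * px,
                "area_px2": r.area,
                "on_border": r.on_border,
            }
            for name in channels:
                row[f"mean_{name}"] = r.mean_intensity[name]
                row[f"bg_{name}"] = bg[name]
            rows.append(row)
    table = pd.DataFrame(rows)
    if return_labels:
        return table, label_stack
    return table


def track_nuclei(
    nuclei: pd.DataFrame, tracking_params: TrackingParams | None = None
) -> list[Track]:
    """Build division-annotated tracks from a quantified nucleus table."""
    tracking_params = tracking_params or TrackingParams()
    tracks = build_tracks(nuclei, tracking_params)
    last_frame = int(nuclei["frame"].max()) if len(nuclei) else 0
    annotate_divisions(tracks, tracking_params, last_frame=last_frame)
    return tracks


def classify_tracks(
    tracks: list[Track],
    nuclei: pd.DataFrame,
    event_params: EventParams | None = None,
) -> list[PhaseTrace]:
    """Hysteresis-classify the Fucci trace of every track.

    Red/green series are per-frame mean intensities along the track with the
    per-frame channel background subtracted.
    """
    event_params = event_params or EventParams()
    indexed = nuclei.set_index(["frame", "label"])
    traces = []
    for t in tracks:
        red, green = [], []
        for f, lab in zip(t.frames, t.labels):
            row = indexed.loc[(f, lab)]
            red.append(float(row["mean_red"]) - float(row["bg_red"]))
            green.append(float(row["mean_green"]) - float(row["bg_green"]))
        traces.append(
            classify_trace(
                t,
                np.array(red),
                np.array(green),
                on_threshold=event_params.on_ratio,
                off_threshold=event_params.off_ratio,
            )
        )
    return traces


@dataclass
class MovieAnalysis:
    nuclei: pd.DataFrame
    tracks: list[Track]
    traces: list[PhaseTrace]
    counts: EventCounts
    geminin_percent: pd.Series


def analyze_stack(
    stack: ImageStack,
    seg_params: SegmentationParams | None = None,
    tracking_params: TrackingParams | None = None,
    event_params: EventParams | None = None,
    frame_area_mm2: float | None = None,
) -> MovieAnalysis:
    """Full quantification of one rendered movie."""
    event_params = event_params or EventParams()
    nuclei = quantify_stack(stack, seg_params)
    tracks = track_nuclei(nuclei, tracking_params)
    traces = classify_tracks(tracks, nuclei, event_params)
    if frame_area_mm2 is None:
        H, W = stack.data.shape[-2:]
        frame_area_mm2 = (H * stack.pixel_size_um) * (W * stack.pixel_size_um) / 1e6
    counts = count_cycle_events(
        traces,
        frame_interval_h=stack.frame_interval_min / 60.0,
        n_frames=stack.n_frames,
        frame_area_mm2=frame_area_mm2,
        bin_hours=event_params.bin_hours,
    )
    geminin = geminin_fraction_series(
        nuclei, green_threshold=event_params.green_positive_threshold
    )
    return MovieAnalysis(
        nuclei=nuclei, tracks=tracks, traces=traces, counts=counts,
        geminin_percent=geminin,
    )
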