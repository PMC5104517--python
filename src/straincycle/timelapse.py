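"""Time-lapse orchestration: initialize, treat, advance, render, log truth."""

from __future__ import annotations

import numpy as np

from .imaging import ImageStack, frame_shape, render_frame
from .params import CycleParams, FieldParams, ImagingParams
from .simulate import (
    Condition,
    GroundTruthTable,
    MonolayerState,
    advance_state,
    apply_stretch,
    build_ground_truth,
    equilibrate_cycle,
    ground_truth_row,
    initialize_quiescent_monolayer,
)

__all__ = ["simulate_timelapse"]


def simulate_timelapse(
    condition: Condition,
    duration_h: float,
    frame_interval_min: float = 15.0,
    seed: int = 0,
    imaging: ImagingParams | None = None,
    cycle_params: CycleParams | None = None,
    field_params: FieldParams | None = None,
    render: bool = True,
    equilibrate: bool = True,
    state: MonolayerState | None = None,
) -> tuple[ImageStack | None, GroundTruthTable]:
    """Simulate a treated monolayer movie with per-frame ground truth.

    The monolayer is matured into quiescence, the basal cycling pipeline is
    brought to its steady state (``equilibrate``; monolayers under the
    microscope show the basal turnover, not the deep post-maturation
    quiescence), the treatment/strain is applied at its onset time, and the
    state is advanced and rendered frame by frame.  ``render=False`` skips
    image formation and returns ``(None, ground_truth)`` -- useful when only
    simulator-level quantities are needed.

    A pre-built ``state`` (e.g. with custom parameters) bypasses
    initialization.  Deterministic given ``(condition, seed, params)``.
    """
    if duration_h < 0:
        raise ValueError("duration must be non-negative")
    imaging = imaging or ImagingParams()
    imaging.frame_interval_min = frame_interval_min
    if state is None:
        state = initialize_quiescent_monolayer(
            seed=seed, params=cycle_params, field_params=field_params
        )
        if equilibrate:
            equilibrate_cycle(state)
    render_rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    shape = frame_shape(state.field_size, imaging)

    dt = frame_interval_min / 60.0
    n_frames = int(round(duration_h / dt)) + 1
    rows: list[tuple] = []
    frames: list[np.ndarray] = []
    stretched = not condition.strain_applied
    for frame in range(n_frames):
        if not stretched and state.time >= condition.strain_onset_time:
            apply_stretch(state, condition.stretch_factor)
            stretched = True
        rows.extend(ground_truth_row(frame, c) for c in state.cells)
        if render:
            frames.append(render_frame(state, imaging, rng=render_rng, shape=shape))
        if frame < n_frames - 1:
            advance_state(state, dt, condition)

    truth = build_ground_truth(rows, state.events)
    stack = None
    if render:
        stack = ImageStack(
            data=np.stack(frames),
            pixel_size_um=imaging.pixel_size_um,
            frame_interval_min=frame_interval_min,
        )
    return stack, truth
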