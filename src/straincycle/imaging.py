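"""Image formation: render monolayer states into multichannel frames.

Each nucleus is an isotropic Gaussian spot (sigma = half the nuclear radius).
Channel amplitudes: the nuclear stain is constant per cell; the red (mKO2-
Cdt1) and green (mAG-Geminin) channels scale with the cell's fluorophore
levels.  Shot noise is Poisson on the expected photon count, followed by
additive Gaussian read noise and clipping to the camera bit depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ImagingParams
from .simulate import Condition, MonolayerState, effective_activity

__all__ = ["ImageStack", "render_frame", "render_marker_snapshot", "frame_shape"]

CHANNELS = ("nuclear", "red", "green")


@dataclass
class ImageStack:
    """A T x C x H x W intensity stack with physical metadata."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channels: tuple[str, ...] = CHANNELS

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str, frame: int) -> np.ndarray:
        return self.data[frame, self.channels.index(name)]


def frame_shape(field_size: tuple[float, float], imaging: ImagingParams) -> tuple[int, int]:
    w, h = field_size
    return (
        int(round(h / imaging.pixel_size_um)),
        int(round(w / imaging.pixel_size_um)),
    )


def _add_spot(canvas: np.ndarray, px: float, py: float, amp: float, sigma: float) -> None:
    """Accumulate one Gaussian spot into ``canvas`` (float, H x W)."""
    if amp <= 0:
        return
    H, W = canvas.shape
    r = int(math.ceil(4.0 * sigma))
    x0, x1 = int(math.floor(px)) - r, int(math.floor(px)) + r + 1
    y0, y1 = int(math.floor(py)) - r, int(math.floor(py)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, W)
    y0c, y1c = max(y0, 0), min(y1, H)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - px
    ys = np.arange(y0c, y1c) - py
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    canvas[y0c:y1c, x0c:x1c] += amp * g


def _apply_noise(
    expected: np.ndarray, imaging: ImagingParams, rng: np.random.Generator | None
) -> np.ndarray:
    out = expected
    if rng is not None and imaging.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if rng is not None and imaging.read_noise > 0:
        out = out + rng.normal(0.0, imaging.read_noise, size=out.shape)
    top = 2**imaging.bit_depth - 1
    return np.clip(np.round(out), 0, top).astype(np.uint16)


def render_frame(
    state: MonolayerState,
    imaging: ImagingParams | None = None,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one three-channel frame (nuclear, red, green) as C x H x W uint16.

    ``rng=None`` renders the noise-free expectation (background plus spots);
    ``shape`` fixes the pixel grid (otherwise derived from the field size, so
    a stretched state would change the canvas -- time-lapse drivers should fix
    the shape at the unstretched field of view).
    """
    imaging = imaging or ImagingParams()
    H, W = shape or frame_shape(state.field_size, imaging)
    sigma = imaging.spot_sigma_px
    px_size = imaging.pixel_size_um
    canvases = np.full((3, H, W), float(imaging.background))
    for cell in state.cells:
        px, py = cell.x / px_size, cell.y / px_size
        _add_spot(canvases[0], px, py, imaging.nuclear_amp, sigma)
        _add_spot(canvases[1], px, py, imaging.red_gain * cell.red_level, sigma)
        _add_spot(canvases[2], px, py, imaging.green_gain * cell.green_level, sigma)
    return np.stack([_apply_noise(c, imaging, rng) for c in canvases])


def render_marker_snapshot(
    state: MonolayerState,
    marker_gain: float,
    imaging: ImagingParams | None = None,
    condition: Condition | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a two-channel snapshot (nuclear + generic activity marker).

    The marker amplitude of each cell is ``marker_gain`` times its activity --
    effective activity under ``condition`` at the state's current time if a
    condition is given, otherwise the intrinsic activity.  Models snapshot
    immunofluorescence readouts that report signalling activity per cell.
    """
    imaging = imaging or ImagingParams()
    H, W = frame_shape(state.field_size, imaging)
    sigma = imaging.spot_sigma_px
    px_size = imaging.pixel_size_um
    canvases = np.full((2, H, W), float(imaging.background))
    for cell in state.cells:
        a = (
            effective_activity(cell.activity, state.time, condition, state.params)
            if condition is not None
            else cell.activity
        )
        px, py = cell.x / px_size, cell.y / px_size
        _add_spot(canvases[0], px, py, imaging.nuclear_amp, sigma)
        _add_spot(canvases[1], px, py, marker_gain * a, sigma)
    return np.stack([_apply_noise(c, imaging, rng) for c in canvases])
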