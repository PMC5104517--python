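"""File formats: multi-page TIFF stacks with sidecar metadata, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import CHANNELS, ImageStack
from .simulate import GroundTruthTable

__all__ = [
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_nuclei_csv",
]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a T x C x H x W stack as 16-bit multi-page TIFF (T-major page
    order, then channel) plus a JSON metadata sidecar."""
    path = Path(path)
    T, C, H, W = stack.data.shape
    pages = stack.data.reshape(T * C, H, W)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "n_frames": T,
        "n_channels": C,
        "channels": list(stack.channels),
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_min": stack.frame_interval_min,
        "page_order": "frame-major, then channel",
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    T, C = meta["n_frames"], meta["n_channels"]
    data = np.asarray(pages).reshape(T, C, *pages.shape[-2:])
    return ImageStack(
        data=data,
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_min=meta["frame_interval_min"],
        channels=tuple(meta.get("channels", CHANNELS)),
    )


def write_ground_truth(truth: GroundTruthTable, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells_path = out / "cells.csv"
    events_path = out / "events.csv"
    truth.cells.to_csv(cells_path, index=False)
    truth.events.to_csv(events_path, index=False)
    return cells_path, events_path


def read_nuclei_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "label", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nuclei table missing columns: {sorted(missing)}")
    return df
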