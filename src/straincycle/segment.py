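"""Nuclear segmentation and per-nucleus / cytoplasmic intensity quantification.

The segmentation recipe is the classical pipeline for a nuclear stain:
Gaussian smoothing, local background subtraction, global Otsu threshold, hole
filling, distance-transform watershed to split touching nuclei, and a minimum
object size filter.  Intensities are quantified as the per-label mean over
each analysed channel; cytoplasmic intensity is the mean over all pixels that
do not belong to a (dilated) nuclear object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential, watershed
from skimage.transform import resize

from .params import SegmentationParams

__all__ = [
    "NucleusRecord",
    "CytoplasmMeasurement",
    "segment_nuclei",
    "measure_nuclei",
    "measure_cytoplasm",
    "classify_positive",
    "estimate_background",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus in one frame.

    Coordinates are 0-based pixel positions, x rightward and y downward
    (image-array convention); ``mean_intensity`` maps channel name to the
    mean pixel value over the label.
    """

    frame: int
    label: int
    x: float
    y: float
    area: int
    mean_intensity: dict[str, float] = field(default_factory=dict)
    on_border: bool = False


@dataclass
class CytoplasmMeasurement:
    frame: int
    mean_intensity: float
    n_pixels: int


def estimate_background(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Smooth local background estimate (grey opening on a downscaled copy).

    A fast stand-in for a rolling-ball filter of the given radius: the image
    is downscaled, opened with a disk, rescaled, and capped at the original
    intensities so the estimate never exceeds the image.
    """
    if radius_px <= 0:
        return np.zeros_like(image, dtype=float)
    factor = max(1, int(radius_px // 6))
    small = image[::factor, ::factor].astype(float)
    r = max(1, int(round(radius_px / factor)))
    opened = ndi.grey_opening(small, footprint=disk(r))
    bg = resize(opened, image.shape, order=1, preserve_range=True)
    return np.minimum(bg, image)


def segment_nuclei(
    image: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Segment nuclei from a single-channel 2D image.

    Returns the label image (0 background, labels 1..N) and one
    :class:`NucleusRecord` per object with geometry filled in; intensity
    fields are populated separately by :func:`measure_nuclei`.  Objects
    touching the image border are kept but flagged.
    """
    params = params or SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got shape {image.shape}")
    img = image.astype(float)
    if params.smooth_sigma_px > 0:
        img = gaussian(img, sigma=params.smooth_sigma_px, preserve_range=True)
    img = img - estimate_background(img, params.background_radius_px)

    empty = np.zeros(image.shape, dtype=np.int32)
    if np.ptp(img) == 0:
        return empty, []
    thr = threshold_otsu(img)
    # robust noise floor: Otsu must clear it, otherwise the frame is empty
    noise = 1.4826 * np.median(np.abs(img - np.median(img)))
    if noise > 0 and thr < params.min_foreground_snr * noise:
        return empty, []
    mask = ndi.binary_fill_holes(img > thr)
    if not mask.any():
        return empty, []

    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance,
        min_distance=params.min_seed_separation_px,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=mask)

    # size filter and sequential relabel
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < params.min_area_px)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)

    H, W = labels.shape
    records = []
    for prop in regionprops(labels):
        cy, cx = prop.centroid
        y0, x0, y1, x1 = prop.bbox
        records.append(
            NucleusRecord(
                frame=0,
                label=prop.label,
                x=float(cx),
                y=float(cy),
                area=int(prop.area),
                on_border=(y0 == 0 or x0 == 0 or y1 == H or x1 == W),
            )
        )
    return labels, records


def measure_nuclei(
    label_image: np.ndarray,
    channel_images: dict[str, np.ndarray],
    records: list[NucleusRecord] | None = None,
    frame: int = 0,
) -> list[NucleusRecord]:
    """Per-label mean intensity of each channel, plus area and centroid.

    Results are independent of the labelling permutation; the centroid is the
    intensity-unweighted centroid of the label mask.
    """
    label_image = np.asarray(label_image)
    for name, img in channel_images.items():
        if np.asarray(img).shape != label_image.shape:
            raise ValueError(
                f"channel {name!r} shape {np.asarray(img).shape} does not match "
                f"label image shape {label_image.shape}"
            )
    if records is None:
        records = []
        for prop in regionprops(label_image.astype(np.int32)):
            cy, cx = prop.centroid
            records.append(
                NucleusRecord(
                    frame=frame, label=prop.label, x=float(cx), y=float(cy),
                    area=int(prop.area),
                )
            )
    index = [r.label for r in records]
    for name, img in channel_images.items():
        means = ndi.mean(np.asarray(img, dtype=float), labels=label_image, index=index)
        for rec, m in zip(records, np.atleast_1d(means)):
            rec.mean_intensity[name] = float(m)
    for rec in records:
        rec.frame = frame
    return records


def measure_cytoplasm(
    label_image: np.ndarray,
    channel_image: np.ndarray,
    nuclear_dilation_px: int = 2,
    frame: int = 0,
) -> CytoplasmMeasurement:
    """Whole-image cytoplasmic intensity: mean over non-nuclear pixels.

    The nuclear mask is dilated by ``nuclear_dilation_px`` to exclude the
    perinuclear halo; the measurement is the mean of the complement.
    """
    label_image = np.asarray(label_image)
    channel_image = np.asarray(channel_image, dtype=float)
    if channel_image.shape != label_image.shape:
        raise ValueError("label image and channel image shapes differ")
    if nuclear_dilation_px < 0:
        raise ValueError("dilation must be non-negative")
    mask = label_image > 0
    if nuclear_dilation_px > 0 and mask.any():
        mask = ndi.binary_dilation(mask, structure=disk(nuclear_dilation_px))
    complement = ~mask
    n = int(complement.sum())
    if n == 0:
        raise ValueError("no cytoplasmic pixels left after nuclear dilation")
    return CytoplasmMeasurement(
        frame=frame,
        mean_intensity=float(channel_image[complement].mean()),
        n_pixels=n,
    )


def classify_positive(
    records: list[NucleusRecord], channel: str, threshold: float
) -> tuple[list[bool], float]:
    """Threshold nuclei into positive/negative for a channel.

    A record is positive iff its mean intensity strictly exceeds the
    threshold; returns the per-record calls and the percent positive.  The
    threshold must be held constant between compared conditions -- that rule
    is the caller's contract, enforced in the statistics layer by comparing
    percentages computed with a single threshold value.
    """
    if not records:
        raise ValueError("cannot compute a percentage over zero nuclei")
    calls = [r.mean_intensity[channel] > threshold for r in records]
    return calls, 100.0 * sum(calls) / len(calls)
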