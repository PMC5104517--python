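"""Equi-biaxial strain estimation from point patterns.

Two estimators mirror the stretcher calibration workflow:

* ``strain_from_beads`` -- a closed-form least-squares similarity (isotropic
  scale + translation) fit to matched fiducial-bead positions before/after
  pressure, reporting ``100 * (scale - 1)`` percent strain;
* ``strain_from_dnn`` -- the live-cell analogue: the fractional increase of
  the nearest-neighbour distance metric (mean distance from each nucleus
  centroid to its 7 nearest neighbours) between two unmatched point sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["StrainEstimate", "dnn7", "strain_from_dnn", "strain_from_beads"]


@dataclass
class StrainEstimate:
    percent_strain: float
    method: str  # "beads" or "dnn7"
    n_points: int
    per_cell_values: Optional[np.ndarray] = None  # dnn7 only (post-set values, um)
    #: per-axis scale residual diagnostic for the bead fit (x scale, y scale);
    #: large anisotropy flags a violation of the equi-biaxial assumption
    axis_scales: Optional[tuple[float, float]] = None


def dnn7(centroids: np.ndarray, k: int = 7) -> tuple[np.ndarray, float]:
    """Per-point mean distance to the ``k`` nearest other points.

    Requires at least ``k + 1`` points.  Returns the per-point values and
    their population mean.  Uniform scaling of the point set by ``s``
    multiplies every value by ``s``.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) < k + 1:
        raise ValueError(f"need at least {k + 1} points for a {k}-neighbour metric")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)  # first neighbour is the point itself
    values = dists[:, 1:].mean(axis=1)
    return values, float(values.mean())


def strain_from_dnn(
    centroids_pre: np.ndarray, centroids_post: np.ndarray, k: int = 7
) -> StrainEstimate:
    """Percent strain as the fractional increase of the mean DNN metric.

    The two centroid sets need not be matched (different nuclei may be
    detected before and after stretch); each must independently satisfy the
    ``dnn7`` precondition.
    """
    _, mean_pre = dnn7(centroids_pre, k=k)
    values_post, mean_post = dnn7(centroids_post, k=k)
    pct = 100.0 * (mean_post - mean_pre) / mean_pre
    return StrainEstimate(
        percent_strain=pct,
        method="dnn7",
        n_points=len(np.asarray(centroids_post).reshape(-1, 2)),
        per_cell_values=values_post,
    )


def strain_from_beads(
    pre_positions: np.ndarray, post_positions: np.ndarray
) -> StrainEstimate:
    """Least-squares isotropic similarity scale between matched point sets.

    Fits ``post = s * (pre - c) + c + t`` in closed form (scale about the
    common centroid plus translation):

        s = sum((pre - pre_mean) . (post - post_mean)) / sum(|pre - pre_mean|^2)

    and reports ``100 * (s - 1)``.  Exact on noiseless similarity transforms
    and invariant to rigid translation of either set.
    """
    pre = np.asarray(pre_positions, dtype=float).reshape(-1, 2)
    post = np.asarray(post_positions, dtype=float).reshape(-1, 2)
    if pre.shape != post.shape:
        raise ValueError("bead lists must be matched (same length)")
    if len(pre) < 3:
        raise ValueError("similarity fit requires at least 3 matched beads")
    a = pre - pre.mean(axis=0)
    b = post - post.mean(axis=0)
    denom = float((a**2).sum())
    if denom == 0.0:
        raise ValueError("pre positions have zero variance; scale is undetermined")
    s = float((a * b).sum()) / denom
    # anisotropy diagnostic: independent per-axis scales
    axis_scales = tuple(
        float((a[:, i] * b[:, i]).sum() / (a[:, i] ** 2).sum())
        if (a[:, i] ** 2).sum() > 0
        else np.nan
        for i in range(2)
    )
    return StrainEstimate(
        percent_strain=100.0 * (s - 1.0),
        method="beads",
        n_points=len(pre),
        axis_scales=axis_scales,
    )
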