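"""Nuclear intensity metrics on z-projections.

Signal intensity statistics are taken over a nuclear region of interest on
the maximum-intensity z-projection of each 3D frame.  The heterochromatin
index is the coefficient of variation of the signal inside the ROI,

    index = SD(intensity) / mean(intensity) * 100,

a texture measure: a nucleus with bright punctate foci over dim
nucleoplasm has high intensity variance relative to its mean, a uniformly
stained nucleus scores near zero.  The index is invariant under intensity
gain but not under an additive offset, so background subtraction (off by
default) is exposed explicitly.  SD uses the sample convention (n-1
denominator, configurable): the convention is not dictated by the
definition and n-1 matches common imaging-software defaults.

ROIs are boolean masks; an Otsu-threshold automatic ROI is provided for
pipeline use as a stand-in for manually drawn outlines (manual masks take
precedence whenever supplied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .synthdata import ImageStack4D

__all__ = [
    "NucleusROI",
    "NucleusMetrics",
    "z_project",
    "auto_roi",
    "nucleus_metrics",
    "metrics_timecourse",
]


@dataclass
class NucleusROI:
    """Boolean nucleus mask on the 2D z-projection, with pixel size in µm."""

    mask: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)  # (y, x) µm/px

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum() * self.pixel_size[0] * self.pixel_size[1])


@dataclass
class NucleusMetrics:
    """Intensity statistics and geometry for one nucleus at one time."""

    mean_intensity: float
    sd_intensity: float
    heterochromatin_index: float  # percent; NaN when undefined
    area: float  # µm²
    index_defined: bool = True


def z_project(volume: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along the z axis of a 3D volume."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected 3D volume, got {volume.ndim}D")
    return volume.max(axis=0)


def auto_roi(
    image2d: np.ndarray, pixel_size: tuple[float, float] = (1.0, 1.0)
) -> NucleusROI:
    """Automatic nucleus ROI: Otsu threshold, largest component, filled."""
    image2d = np.asarray(image2d, dtype=float)
    if image2d.ndim != 2:
        raise ValueError("auto_roi expects a 2D projection")
    mask = image2d > threshold_otsu(image2d)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no foreground found for automatic ROI")
    largest = np.argmax(ndimage.sum_labels(mask, labels, range(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return NucleusROI(mask, pixel_size)


def nucleus_metrics(
    image2d: np.ndarray,
    roi: NucleusROI,
    ddof: int = 1,
    background: float = 0.0,
) -> NucleusMetrics:
    """Mean, SD, heterochromatin index and area over the ROI pixels.

    ``background`` is an optional constant offset subtracted before the
    statistics (the index is offset-sensitive).  A zero mean leaves the
    index undefined: it is reported as NaN with ``index_defined=False``
    rather than as an infinity.
    """
    image2d = np.asarray(image2d, dtype=float)
    if image2d.shape != roi.mask.shape:
        raise ValueError("ROI mask shape does not match image")
    pixels = image2d[roi.mask] - background
    mean = float(pixels.mean())
    sd = float(pixels.std(ddof=ddof)) if pixels.size > ddof else 0.0
    if mean == 0.0:
        return NucleusMetrics(mean, sd, float("nan"), roi.area_um2, False)
    return NucleusMetrics(mean, sd, sd / mean * 100.0, roi.area_um2, True)


def metrics_timecourse(
    stack: ImageStack4D,
    rois: list[NucleusROI] | NucleusROI | None = None,
    group: str = "",
    ddof: int = 1,
    background: float = 0.0,
) -> pd.DataFrame:
    """Per-frame nucleus metrics as a tidy table.

    ``rois`` may be one ROI per frame, a single ROI reused for all frames,
    or None to derive an automatic Otsu ROI per frame.  Columns:
    t_min, group, mean, sd, index, area_um2.
    """
    n = stack.n_frames
    pixel_size = (stack.voxel_size[1], stack.voxel_size[2])
    if rois is None:
        roi_list = [
            auto_roi(z_project(stack.data[t]), pixel_size) for t in range(n)
        ]
    elif isinstance(rois, NucleusROI):
        roi_list = [rois] * n
    else:
        if len(rois) != n:
            raise ValueError(
                f"got {len(rois)} ROIs for {n} frames (need one per frame)"
            )
        roi_list = list(rois)
    rows = []
    for t, roi in zip(range(n), roi_list):
        m = nucleus_metrics(
            z_project(stack.data[t]), roi, ddof=ddof, background=background
        )
        rows.append(
            {
                "t_min": float(stack.times_min[t]),
                "group": group,
                "mean": m.mean_intensity,
                "sd": m.sd_intensity,
                "index": m.heterochromatin_index,
                "area_um2": m.area,
            }
        )
    return pd.DataFrame(rows)
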