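"""Image-quality metrics: HU conversion, CNR, CT-number linearity and error.

CT numbers use the standard rescaling HU = 1000 (mu - mu_water)/mu_water.
The linearity slope is the ordinary least-squares regression of measured
insert CT# on the true CT#, and the contrast-to-noise ratio follows the
two-ROI convention (mean difference over background standard deviation)
with a signal ROI of 3/4 the insert radius.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HU, MU_MM, VolumeImage, VoxelGrid

__all__ = [
    "ROISpec",
    "to_hu",
    "cnr",
    "linearity_slope",
    "mean_abs_ct_error",
    "roi_mask",
    "roi_stats",
]


@dataclass(frozen=True)
class ROISpec:
    """Cylindrical region of interest: center (mm, in-plane), radius (mm)
    and an inclusive z index range."""

    center_mm: tuple[float, float]
    radius_mm: float
    z_range: tuple[int, int]


def to_hu(volume: VolumeImage, mu_water_ref: float) -> VolumeImage:
    """Convert an attenuation volume to Hounsfield units."""
    if mu_water_ref <= 0:
        raise ValueError("water reference attenuation must be positive")
    if volume.unit == HU:
        return volume
    vals = 1000.0 * (volume.values - mu_water_ref) / mu_water_ref
    return VolumeImage(vals, volume.grid, HU)


def roi_mask(grid: VoxelGrid, roi: ROISpec) -> np.ndarray:
    x = grid.centers(0)[:, None]
    y = grid.centers(1)[None, :]
    inplane = (x - roi.center_mm[0]) ** 2 + (y - roi.center_mm[1]) ** 2 \
        <= roi.radius_mm**2
    mask = np.zeros(grid.shape, dtype=bool)
    z0, z1 = roi.z_range
    mask[:, :, z0:z1 + 1] = inplane[:, :, None]
    return mask


def roi_stats(volume: VolumeImage, roi: ROISpec) -> tuple[float, float, int]:
    m = roi_mask(volume.grid, roi)
    vals = volume.values[m]
    if vals.size == 0:
        raise ValueError("ROI lies outside the volume")
    return float(vals.mean()), float(vals.std(ddof=1)), int(vals.size)


def cnr(volume: VolumeImage, roi_signal: ROISpec, roi_background: ROISpec,
        min_voxels: int = 20) -> float:
    """(mean_signal - mean_background) / std_background."""
    ms, _, ns = roi_stats(volume, roi_signal)
    mb, sb, nb = roi_stats(volume, roi_background)
    if ns < min_voxels or nb < min_voxels:
        raise ValueError(f"ROIs need at least {min_voxels} voxels "
                         f"(got {ns} and {nb})")
    if sb <= 0:
        raise ValueError("background standard deviation is zero "
                         "(degenerate noiseless input)")
    return (ms - mb) / sb


def linearity_slope(measured_hu, true_hu) -> tuple[float, float, float]:
    """OLS regression of measured on true CT#; returns (slope, intercept, r)."""
    m = np.asarray(measured_hu, dtype=float)
    t = np.asarray(true_hu, dtype=float)
    if m.shape != t.shape or m.ndim != 1:
        raise ValueError("need matching 1-D measured/true arrays")
    if m.size < 3:
        raise ValueError("need at least 3 inserts for a regression")
    if np.ptp(t) < 1e-12:
        raise ValueError("true CT# values are constant")
    slope, intercept = np.polyfit(t, m, 1)
    r = float(np.corrcoef(t, m)[0, 1])
    return float(slope), float(intercept), r


def mean_abs_ct_error(measured_hu, true_hu) -> float:
    """Mean over inserts of |measured - true|, in HU."""
    m = np.asarray(measured_hu, dtype=float)
    t = np.asarray(true_hu, dtype=float)
    if m.shape != t.shape:
        raise ValueError("measured/true length mismatch")
    return float(np.mean(np.abs(m - t)))
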