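"""Low-frequency artifact correction (shading correction) on projections.

The algorithm removes the low-frequency projection error caused by scatter
and flood-normalisation (gain saturation) without touching anatomical
detail:

1. reconstruct the measured projections with FDK;
2. flag the cone-artifact region (unity-volume round-trip test) and replace
   it by TV inpainting, so the corrupted region does not propagate through
   the forward projection;
3. segment the volume into air / soft tissue / bone by histogram
   thresholding;
4. polychromatically re-project the segmented volume with reference material
   attenuations, giving an idealised, degradation-free projection set;
5. TV-smooth the measured-minus-ideal difference per view -- the smooth
   residual is the shading estimate, while structures absent from the crude
   segmentation stay out of it -- and subtract it from the measurement.

On undegraded inputs the difference carries no low-frequency component and
the correction is (near) null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .fdk import cone_artifact_mask, fdk_reconstruct
from .geometry import (
    LINE_INTEGRAL,
    ConeBeamGeometry,
    ProjectionStack,
    VolumeImage,
    VoxelGrid,
)
from .projector import combine_polychromatic, forward_project_values
from .spectra import EnergySpectrum, MaterialTable, effective_mu
from .tv import tv_inpaint, tv_smooth_views

__all__ = [
    "SegmentationMap",
    "SegmentationError",
    "segment_by_histogram",
    "ideal_projections",
    "lfac_correct",
    "inpaint_cone_region",
    "run_lfac",
    "DEFAULT_TV_WEIGHT",
]

# Chambolle weight for smoothing the projection difference; in line-integral
# units.  Chosen so the smoothed difference retains only features much wider
# than ~20 detector pixels (the shading field) and flattens segmentation-
# mismatch structures.
DEFAULT_TV_WEIGHT = 0.35

AIR, SOFT, BONE = 0, 1, 2


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationMap:
    """Three-class labeling {air, soft, bone} of a reconstruction, with the
    thresholds (mm^-1) that produced it."""

    labels: np.ndarray
    thresholds: tuple[float, float]
    grid: VoxelGrid


def segment_by_histogram(volume: VolumeImage, n_bins: int = 256) -> SegmentationMap:
    """Histogram-threshold a reconstruction into air / soft tissue / bone.

    The air/soft threshold is the deepest valley between the two dominant
    histogram peaks; the soft/bone threshold is Otsu's threshold over the
    remaining (non-air) values.  A unimodal histogram (empty scan) raises
    :class:`SegmentationError`.
    """
    vals = volume.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("volume contains non-finite values")
    hist, edges = np.histogram(vals.ravel(), bins=n_bins)
    smooth = gaussian_filter1d(hist.astype(float), sigma=2.0)
    floor = max(smooth.max() * 1e-3, 1.0)
    peaks, _ = find_peaks(smooth, height=floor, distance=5,
                          prominence=smooth.max() * 0.02)
    if peaks.size < 2:
        raise SegmentationError(
            "histogram is unimodal; cannot separate air from tissue")
    # two most populated peaks, in value order
    top2 = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
    valley = top2[0] + int(np.argmin(smooth[top2[0]:top2[1] + 1]))
    t_air = float(edges[valley])
    body = vals[vals > t_air]
    if body.size < 10 or np.ptp(body) < 1e-9:
        raise SegmentationError("no tissue voxels above the air threshold")
    t_bone = float(threshold_otsu(body, nbins=n_bins))
    if not t_air < t_bone:
        raise SegmentationError(
            f"thresholds not ordered: air {t_air:.4g} >= bone {t_bone:.4g}")
    # Otsu separates soft tissue from bone only when the tissue histogram is
    # genuinely bimodal; on a shading-dominated continuum it would split one
    # material in half.  Require a strong between-class variance ratio,
    # otherwise keep a single soft-tissue class.
    lo, hi = body[body <= t_bone], body[body > t_bone]
    if lo.size > 1 and hi.size > 1 and body.var() > 0:
        w0 = lo.size / body.size
        sep = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2 / body.var()
    else:
        sep = 0.0
    if sep < 0.80:
        t_bone = float(np.nextafter(vals.max(), np.inf))
    labels = np.full(vals.shape, AIR, dtype=np.int8)
    labels[vals > t_air] = SOFT
    labels[vals > t_bone] = BONE
    return SegmentationMap(labels, (t_air, t_bone), volume.grid)


def ideal_projections(seg: SegmentationMap, spectrum: EnergySpectrum,
                      materials: dict[int, MaterialTable],
                      geom: ConeBeamGeometry) -> ProjectionStack:
    """Polychromatic re-projection of a segmentation with reference materials.

    ``materials`` maps segmentation class -> material; every non-air class
    present in the map must be covered.  Each class contributes an indicator
    volume scaled by its effective (spectrum-weighted) attenuation, projected
    through the polychromatic Beer-Lambert model.
    """
    present = [int(c) for c in np.unique(seg.labels) if c != AIR]
    missing = [c for c in present if c not in materials]
    if missing:
        raise ValueError(f"no material mapped for segmentation class {missing}")
    if not present:
        vals = np.zeros((geom.n_views, geom.det_rows, geom.det_cols))
        return ProjectionStack(vals, LINE_INTEGRAL, geom)
    g_list, mats = [], []
    for c in present:
        mu_bar = effective_mu(materials[c], spectrum)
        ind = (seg.labels == c).astype(np.float64) * mu_bar
        g_list.append(forward_project_values(ind, seg.grid, geom))
        mats.append(materials[c])
    vals = combine_polychromatic(g_list, spectrum, mats)
    return ProjectionStack(vals, LINE_INTEGRAL, geom)


def reference_projections(phantom, spectrum: EnergySpectrum,
                          geom: ConeBeamGeometry,
                          bowtie_profile: np.ndarray | None = None,
                          ) -> ProjectionStack:
    """Ideal degradation-free polychromatic projections of a known phantom
    model (the 'CAD model' route used for phantom experiments, where the
    object's composition is known exactly and no segmentation is needed).

    When the system carries a bowtie filter, pass its profile: the ideal
    reference then includes the bowtie hardening, so the shading correction
    removes only unmodeled degradations (scatter, flood error) and leaves
    the dome effect for the dedicated dome correction.
    """
    if bowtie_profile is not None:
        from .simulate import DegradationModel, simulate_acquisition
        clean = simulate_acquisition(
            phantom, geom, spectrum,
            DegradationModel(bowtie_profile=np.asarray(bowtie_profile)))
        return clean.to_line_integral()
    g_list, mats = [], []
    for lab in phantom.label_ids:
        mat = phantom.material_of_label[lab]
        mu_bar = effective_mu(mat, spectrum)
        ind = (phantom.labels == lab).astype(np.float64) * mu_bar
        g_list.append(forward_project_values(ind, phantom.grid, geom))
        mats.append(mat)
    vals = combine_polychromatic(g_list, spectrum, mats)
    return ProjectionStack(vals, LINE_INTEGRAL, geom)


def lfac_correct(measured: ProjectionStack, ideal: ProjectionStack,
                 tv_weight: float = DEFAULT_TV_WEIGHT) -> ProjectionStack:
    """Subtract the TV-smoothed (measured - ideal) difference from measured."""
    if measured.values.shape != ideal.values.shape:
        raise ValueError("measured/ideal projection shapes differ")
    if measured.domain != LINE_INTEGRAL or ideal.domain != LINE_INTEGRAL:
        raise ValueError("lfac_correct operates on line integrals")
    diff = measured.values - ideal.values
    smooth = tv_smooth_views(diff, weight=tv_weight)
    return ProjectionStack(measured.values - smooth, LINE_INTEGRAL,
                           measured.geometry)


def inpaint_cone_region(volume: VolumeImage, mask: np.ndarray,
                        weight: float | None = None) -> VolumeImage:
    """TV-inpaint the masked (cone-corrupted) voxels; others are unchanged."""
    out = tv_inpaint(volume.values, mask, weight=weight)
    return VolumeImage(out, volume.grid, volume.unit)


def run_lfac(measured: ProjectionStack, spectrum: EnergySpectrum,
             materials: dict[int, MaterialTable], grid: VoxelGrid,
             tv_weight: float = DEFAULT_TV_WEIGHT,
             cone_mask: np.ndarray | None = None,
             reference=None,
             ) -> ProjectionStack:
    """Full shading-correction pipeline; returns corrected line integrals.

    ``materials`` maps the segmentation classes SOFT and BONE to reference
    materials (e.g. water/soft tissue and bone).  ``cone_mask`` may be
    passed in when precomputed for the geometry/grid pair.  When the scanned
    object's composition is known (phantom experiments), pass the
    :class:`~cali.phantoms.LabeledPhantom` as ``reference`` to use its exact
    model re-projection instead of the segmentation-based one.
    """
    geom = measured.geometry
    P = measured.to_line_integral()
    if reference is not None:
        ideal = reference_projections(reference, spectrum, geom)
    else:
        recon = fdk_reconstruct(P, grid)
        if cone_mask is None:
            cone_mask = cone_artifact_mask(geom, grid)
        if cone_mask.any() and not cone_mask.all():
            recon = inpaint_cone_region(recon, cone_mask)
        seg = segment_by_histogram(recon)
        ideal = ideal_projections(seg, spectrum, materials, geom)
    return lfac_correct(P, ideal, tv_weight)
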