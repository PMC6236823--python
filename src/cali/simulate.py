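"""Synthetic CBCT acquisition: polychromatic primaries plus a degradation chain.

The simulator emulates the degradations that dominate shading and CT-number
non-linearity in flat-panel CBCT:

1. per-column bowtie-hardened spectra (parabolic aluminium profile),
2. polychromatic Beer-Lambert primaries from per-material path lengths,
3. additive low-frequency scatter (Gaussian-blurred scaled primary, scaled
   to the requested scatter-to-primary ratio at the detector),
4. a multiplicative flood-field saturation error that survives the ideal
   flood normalisation, and
5. Poisson counting noise at a given mean fluence per pixel.

With all degradation fields neutral the chain is the identity: -log I equals
the polychromatic line integrals exactly.

`calibrate_degradation` and `calibrate_photons` run 1-D searches that place
the *uncorrected* FDK reconstruction at a requested operating point
(linearity slope, or acrylic-insert CNR) so correction experiments start
from a reproducible degradation level.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .fdk import bowtie_spectra, fdk_reconstruct
from .geometry import INTENSITY, ConeBeamGeometry, ProjectionStack, VoxelGrid
from .metrics import cnr, linearity_slope, roi_stats, to_hu
from .phantoms import LabeledPhantom
from .projector import forward_project_values
from .spectra import EnergySpectrum, effective_mu, load_material, normalize_spectrum

__all__ = [
    "DegradationModel",
    "default_bowtie",
    "default_flood_error",
    "compute_path_lengths",
    "simulate_acquisition",
    "uncorrected_catphan_metrics",
    "calibrate_degradation",
    "calibrate_photons",
]


def default_bowtie(geom: ConeBeamGeometry, edge_mm: float = 6.0) -> np.ndarray:
    """Parabolic aluminium bowtie path profile (mm per detector column):
    zero on the central ray, ``edge_mm`` at the widest column."""
    u = geom.u_coords_mm()
    umax = np.abs(u).max()
    return edge_mm * (u / umax) ** 2


def default_flood_error(geom: ConeBeamGeometry, amplitude: float = 0.02) -> np.ndarray:
    """Smooth multiplicative flood/gain error map (detector saturation
    stand-in): a central Gaussian bump of the given relative amplitude."""
    u = geom.u_coords_mm()
    v = geom.v_coords_mm()
    umax = max(np.abs(u).max(), 1.0)
    vmax = max(np.abs(v).max(), 1.0)
    U, V = np.meshgrid(v, u, indexing="ij")
    return 1.0 + amplitude * np.exp(-((V / (0.6 * umax)) ** 2
                                      + (U / (0.6 * vmax)) ** 2))


@dataclass(frozen=True)
class DegradationModel:
    """Knobs of the acquisition degradation chain (all off by default)."""

    scatter_to_primary: float = 0.0
    scatter_kernel_fwhm_mm: float = 80.0
    bowtie_profile: np.ndarray | None = None  # mm Al per detector column
    flood_saturation_error: np.ndarray | None = None  # (rows, cols), > 0
    photons_per_pixel: float = 0.0  # 0 disables Poisson noise
    seed: int = 0

    def __post_init__(self):
        if self.scatter_to_primary < 0 or self.photons_per_pixel < 0:
            raise ValueError("SPR and photon count must be non-negative")
        if self.flood_saturation_error is not None and \
                np.any(np.asarray(self.flood_saturation_error) <= 0):
            raise ValueError("flood error map must be positive")


def compute_path_lengths(phantom: LabeledPhantom, geom: ConeBeamGeometry,
                         step_mm: float | None = None) -> dict[int, np.ndarray]:
    """Per-label intersection lengths (mm) of every ray, by forward
    projection of the label indicator volumes (air included, so the chain
    is exactly consistent with a projection of the full attenuation map)."""
    out = {}
    for lab in phantom.label_ids:
        ind = (phantom.labels == lab).astype(np.float64)
        out[lab] = forward_project_values(ind, phantom.grid, geom, step_mm)
    return out


def simulate_acquisition(phantom: LabeledPhantom, geom: ConeBeamGeometry,
                         spectrum: EnergySpectrum,
                         degradation: DegradationModel,
                         path_lengths: dict[int, np.ndarray] | None = None,
                         ) -> ProjectionStack:
    """Simulate flood-normalized intensity projections of a labeled phantom."""
    if path_lengths is None:
        path_lengths = compute_path_lengths(phantom, geom)
    s = normalize_spectrum(spectrum)
    if degradation.bowtie_profile is not None:
        shat_col = bowtie_spectra(spectrum, degradation.bowtie_profile, geom)
    else:
        shat_col = np.broadcast_to(s.weights[None, :],
                                   (geom.det_cols, s.n_bins))
    mu_of = {lab: phantom.material_of_label[lab].mu_at(s.energies_keV)
             for lab in path_lengths}

    shape = (geom.n_views, geom.det_rows, geom.det_cols)
    primary = np.zeros(shape)
    for e in range(s.n_bins):
        att = np.zeros(shape)
        for lab, L in path_lengths.items():
            att += mu_of[lab][e] * L
        primary += shat_col[None, None, :, e] * np.exp(-att)

    intensity = primary
    if degradation.scatter_to_primary > 0:
        sigma_pix = degradation.scatter_kernel_fwhm_mm / 2.355 / geom.det_pitch_mm
        scatter = gaussian_filter(
            degradation.scatter_to_primary * primary,
            sigma=(0, sigma_pix, sigma_pix), mode="nearest")
        intensity = intensity + scatter
    if degradation.flood_saturation_error is not None:
        err = np.asarray(degradation.flood_saturation_error, dtype=float)
        if err.shape != (geom.det_rows, geom.det_cols):
            raise ValueError("flood error map shape must match the detector")
        intensity = intensity * err[None, :, :]
    if degradation.photons_per_pixel > 0:
        rng = np.random.default_rng(degradation.seed)
        n = degradation.photons_per_pixel
        counts = rng.poisson(np.maximum(intensity, 0.0) * n)
        intensity = np.maximum(counts, 0.5) / n
    # normalisation by the ideal (error-free, object-free) flood is division
    # by one: the flood saturation error deliberately persists
    return ProjectionStack(intensity, INTENSITY, geom)


def uncorrected_catphan_metrics(phantom: LabeledPhantom, geom: ConeBeamGeometry,
                                spectrum: EnergySpectrum,
                                degradation: DegradationModel,
                                path_lengths: dict[int, np.ndarray] | None = None,
                                ):
    """FDK-reconstruct a degraded simulation and measure slope / MAE / CNR.

    Returns (slope, mae_hu, cnr_acrylic, volume_hu).
    """
    stack = simulate_acquisition(phantom, geom, spectrum, degradation,
                                 path_lengths)
    recon = fdk_reconstruct(stack.to_line_integral(), phantom.grid)
    mu_w = effective_mu(load_material("water"), spectrum)
    vol_hu = to_hu(recon, mu_w)
    measured, true = [], []
    acr_cnr = np.nan
    for ins in phantom.inserts:
        mean, _, _ = roi_stats(vol_hu, ins.roi(phantom.grid))
        measured.append(mean)
        mu_true = effective_mu(phantom.material_of_label[ins.label], spectrum)
        true.append(1000.0 * (mu_true - mu_w) / mu_w)
        if ins.material == "acrylic" and phantom.background_roi is not None:
            try:
                acr_cnr = cnr(vol_hu, ins.roi(phantom.grid),
                              phantom.background_roi)
            except ValueError:
                acr_cnr = np.nan
    slope, _, _ = linearity_slope(measured, true)
    from .metrics import mean_abs_ct_error
    mae = mean_abs_ct_error(measured, true)
    return slope, mae, acr_cnr, vol_hu


def calibrate_degradation(target_slope: float, geom: ConeBeamGeometry,
                          spectrum: EnergySpectrum,
                          phantom: LabeledPhantom,
                          base: DegradationModel | None = None,
                          tol: float = 0.02, max_iter: int = 12,
                          spr_bracket: tuple[float, float] = (0.0, 2.0),
                          ) -> DegradationModel:
    """Bisection over the scatter-to-primary ratio so that the uncorrected
    FDK linearity slope matches ``target_slope`` (within +-0.03; the search
    stops at ``tol``).  Raises if the target is outside the reachable range.
    """
    if not 0.0 < target_slope < 1.0:
        raise ValueError("target slope must lie in (0, 1)")
    if base is None:
        base = DegradationModel()
    paths = compute_path_lengths(phantom, geom)

    def slope_at(spr: float) -> float:
        model = replace(base, scatter_to_primary=spr)
        s, _, _, _ = uncorrected_catphan_metrics(phantom, geom, spectrum,
                                                 model, paths)
        return s

    lo, hi = spr_bracket
    s_lo, s_hi = slope_at(lo), slope_at(hi)
    # slope decreases monotonically with SPR
    if target_slope > s_lo + tol or target_slope < s_hi - tol:
        raise ValueError(
            f"target slope {target_slope} unreachable: SPR in "
            f"[{lo}, {hi}] spans slopes [{s_hi:.3f}, {s_lo:.3f}]")
    if abs(s_lo - target_slope) <= tol:
        return replace(base, scatter_to_primary=lo)
    spr = hi
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        s_mid = slope_at(mid)
        if abs(s_mid - target_slope) <= tol:
            return replace(base, scatter_to_primary=mid)
        if s_mid > target_slope:
            lo = mid
        else:
            hi = mid
        spr = mid
    return replace(base, scatter_to_primary=spr)


def calibrate_photons(target_cnr: float, geom: ConeBeamGeometry,
                      spectrum: EnergySpectrum, phantom: LabeledPhantom,
                      base: DegradationModel,
                      tol: float = 0.1, max_iter: int = 10,
                      log10_bracket: tuple[float, float] = (2.0, 7.0),
                      ) -> DegradationModel:
    """Bisection over the photon fluence so the uncorrected FDK acrylic-insert
    CNR matches ``target_cnr`` (CNR increases with fluence)."""
    paths = compute_path_lengths(phantom, geom)

    def cnr_at(log_n: float) -> float:
        model = replace(base, photons_per_pixel=10.0**log_n)
        _, _, c, _ = uncorrected_catphan_metrics(phantom, geom, spectrum,
                                                 model, paths)
        return c

    lo, hi = log10_bracket
    c_lo, c_hi = cnr_at(lo), cnr_at(hi)
    if not (c_lo < target_cnr < c_hi):
        raise ValueError(
            f"target CNR {target_cnr} unreachable: fluence bracket spans "
            f"CNR [{c_lo:.2f}, {c_hi:.2f}]")
    mid = (lo + hi) / 2
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        c_mid = cnr_at(mid)
        if abs(c_mid - target_cnr) <= tol:
            break
        if c_mid < target_cnr:
            lo = mid
        else:
            hi = mid
    return replace(base, photons_per_pixel=10.0**mid)
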