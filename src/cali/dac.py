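"""Dome/capping artifact correction on reconstructed images.

A bowtie filter hardens the beam toward the fan periphery, so voxels near
the image center are reconstructed from softer (lower-energy) rays and come
out with higher attenuation than peripheral voxels of the same material --
the dome artifact.  The correction remaps every voxel from its locally
sensed mean energy to the global reference spectrum:

* the local mean energy map is obtained by unfiltered energy-dependent
  backprojection of the post-bowtie spectrum
  (:func:`cali.fdk.backproject_energy`);
* for each basis material the *mean attenuation under the locally sensed
  spectrum* is tabulated as a function of mean energy by sweeping the
  bowtie filter thickness -- reconstructed values live on this effective
  (spectrum-weighted) attenuation scale, not on a monochromatic one;
* at each voxel the local nodes interpolate the voxel value into basis
  weights w_i, and the corrected value is sum_i w_i mubar_i(reference),
  with the reference nodes taken at the unfiltered spectrum (whose mean
  energy is the global reference energy).

When the energy map equals the reference energy everywhere the remapping
is the identity; for fixed local energy it is monotone in the input value.
Object self-filtration is deliberately excluded from the energy map (that
part of the hardening is the beam-hardening correction's job); a residual
dark ring at strong bowtie gradients is expected behaviour of the method.
"""
from __future__ import annotations

import numpy as np

from .geometry import MU_MM, VolumeImage
from .spectra import (
    EnergySpectrum,
    MaterialTable,
    effective_mu,
    load_material,
    mean_energy,
    normalize_spectrum,
)

__all__ = ["basis_node_curves", "dac_correct"]


def basis_node_curves(spectrum: EnergySpectrum,
                      materials: list[MaterialTable],
                      filter_material: MaterialTable | None = None,
                      max_filter_mm: float = 40.0,
                      n_samples: int = 48):
    """Mean energy and per-material effective attenuation vs filtration.

    Hardens ``spectrum`` through 0..``max_filter_mm`` of the filter material
    (aluminum by default, matching the energy backprojection) and returns
    ``(energies, node_table)`` where ``energies`` is the mean energy of each
    hardened spectrum (strictly increasing, starting at the unfiltered mean
    energy) and ``node_table[i]`` the corresponding effective attenuation of
    material i.
    """
    filt = filter_material if filter_material is not None else load_material("aluminum")
    s = normalize_spectrum(spectrum)
    mu_f = filt.mu_at(s.energies_keV)
    thickness = np.linspace(0.0, max_filter_mm, n_samples)
    weights = s.weights[None, :] * np.exp(-np.outer(thickness, mu_f))
    weights /= weights.sum(axis=1, keepdims=True)
    energies = weights @ s.energies_keV
    mu_mats = np.stack([m.mu_at(s.energies_keV) for m in materials], axis=0)
    nodes = mu_mats @ weights.T  # (n_materials, n_samples)
    # mean energy is strictly increasing with filtration; guard regardless
    order = np.argsort(energies)
    return energies[order], nodes[:, order]


def dac_correct(volume: VolumeImage, emap: np.ndarray,
                materials: list[MaterialTable],
                spectrum: EnergySpectrum,
                filter_material: MaterialTable | None = None) -> VolumeImage:
    """Remap voxel values from their local mean energy to the global spectrum.

    ``materials`` are the ordered basis materials (increasing attenuation);
    ``emap`` the per-voxel sensed mean energy (keV) on the same grid.  The
    reference is the unfiltered ``spectrum`` (global mean energy), so a
    uniform energy map at that energy leaves the volume unchanged.
    """
    if volume.unit != MU_MM:
        raise ValueError("dac_correct expects an attenuation-map volume")
    emap = np.asarray(emap, dtype=float)
    if emap.shape != volume.values.shape:
        raise ValueError("energy map shape must match the volume")
    M = len(materials)
    if M < 2:
        raise ValueError("need at least two basis materials")
    energies, nodes = basis_node_curves(spectrum, materials, filter_material)
    e_lo, e_hi = energies[0], energies[-1]
    flat_e = emap.ravel()
    if np.any(flat_e < e_lo - 0.51) or np.any(flat_e > e_hi + 1e-6):
        raise ValueError(
            f"energy map values [{flat_e.min():.2f}, {flat_e.max():.2f}] keV "
            f"outside the attainable hardened-spectrum range "
            f"[{e_lo:.2f}, {e_hi:.2f}] keV")
    flat_e = np.clip(flat_e, e_lo, e_hi)
    mu_local = np.stack(
        [np.interp(flat_e, energies, nodes[i]) for i in range(M)], axis=0)
    mu_ref = np.array([effective_mu(m, spectrum) for m in materials])
    f = volume.values.ravel()
    f = np.clip(f, mu_local[0], mu_local[-1])
    out = np.zeros_like(f)
    done = np.zeros(f.shape, dtype=bool)
    for i in range(M - 1):
        lo, hi = mu_local[i], mu_local[i + 1]
        sel = ~done & (f >= lo) & (f <= hi)
        if not np.any(sel):
            continue
        w = (f[sel] - lo[sel]) / np.maximum(hi[sel] - lo[sel], 1e-30)
        out[sel] = (1.0 - w) * mu_ref[i] + w * mu_ref[i + 1]
        done |= sel
    out[~done] = mu_ref[-1]  # numerically above the top node
    return VolumeImage(out.reshape(volume.values.shape), volume.grid, MU_MM)
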