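"""Mono- and polychromatic cone-beam forward projection.

The monochromatic projector returns line integrals of a single attenuation
volume.  The polychromatic projector takes one attenuation-contribution map
per basis material (the T_i volumes of the basis decomposition, in
effective-attenuation units), projects each monochromatically to obtain
g_i, and combines them through the discrete Beer-Lambert mixture

    P_poly = -log sum_E Shat(E) exp(-sum_i sigma_hat_i(E) g_i),

which collapses to sum_i g_i for a monoenergetic spectrum.  By Jensen's
inequality (convexity of exp) P_poly <= sum_i g_i always.
"""
from __future__ import annotations

import numpy as np

from ._kernels import forward_kernel, scatter_backproject_kernel
from .geometry import (
    LINE_INTEGRAL,
    ConeBeamGeometry,
    ProjectionStack,
    VolumeImage,
    VoxelGrid,
)
from .spectra import EnergySpectrum, MaterialTable, normalize_spectrum, sigma_hat

__all__ = [
    "forward_project_mono",
    "forward_project_values",
    "forward_project_poly",
    "combine_polychromatic",
    "adjoint_backproject",
]


def forward_project_values(values: np.ndarray, grid: VoxelGrid,
                           geom: ConeBeamGeometry,
                           step_mm: float | None = None) -> np.ndarray:
    """Raw ray-driven projection of a value array; returns the stack array."""
    vol = np.ascontiguousarray(values, dtype=np.float64)
    if vol.size == 0:
        raise ValueError("empty volume")
    if step_mm is None:
        step_mm = grid.voxel_mm / 2.0
    out = np.zeros((geom.n_views, geom.det_rows, geom.det_cols))
    forward_kernel(
        vol, grid.voxel_mm, *grid.origin_mm,
        geom.source_axis_dist_mm, geom.source_detector_dist_mm,
        geom.det_pitch_mm, geom.det_offset_mm[0], geom.det_offset_mm[1],
        np.radians(geom.angles_deg), step_mm, out,
    )
    return out


def forward_project_mono(volume: VolumeImage, geom: ConeBeamGeometry,
                         step_mm: float | None = None) -> ProjectionStack:
    """Line integrals of an attenuation volume (mm^-1 -> dimensionless)."""
    vals = forward_project_values(volume.values, volume.grid, geom, step_mm)
    return ProjectionStack(vals, LINE_INTEGRAL, geom)


def combine_polychromatic(g_list: list[np.ndarray],
                          spectrum: EnergySpectrum,
                          materials: list[MaterialTable]) -> np.ndarray:
    """-log sum_E Shat(E) exp(-sum_i sigma_hat_i(E) g_i) from projected maps."""
    if len(g_list) != len(materials):
        raise ValueError(
            f"{len(g_list)} material maps but {len(materials)} materials")
    s = normalize_spectrum(spectrum)
    sig = [sigma_hat(m, spectrum) for m in materials]
    intensity = np.zeros_like(g_list[0])
    for e in range(s.n_bins):
        att = np.zeros_like(g_list[0])
        for g, sg in zip(g_list, sig):
            att += sg[e] * g
        intensity += s.weights[e] * np.exp(-att)
    return -np.log(intensity)


def forward_project_poly(material_volumes: list[VolumeImage],
                         spectrum: EnergySpectrum,
                         materials: list[MaterialTable],
                         geom: ConeBeamGeometry,
                         step_mm: float | None = None) -> ProjectionStack:
    """Polychromatic projection of per-material attenuation-contribution maps."""
    if len(material_volumes) != len(materials):
        raise ValueError(
            f"{len(material_volumes)} maps but {len(materials)} materials")
    g_list = [forward_project_values(v.values, v.grid, geom, step_mm)
              for v in material_volumes]
    vals = combine_polychromatic(g_list, spectrum, materials)
    return ProjectionStack(vals, LINE_INTEGRAL, geom)


def adjoint_backproject(stack_values: np.ndarray, grid: VoxelGrid,
                        geom: ConeBeamGeometry,
                        step_mm: float | None = None) -> np.ndarray:
    """Exact adjoint of :func:`forward_project_values` (used by the
    iterative TV reconstruction; not a tomographic inverse)."""
    if step_mm is None:
        step_mm = grid.voxel_mm / 2.0
    out = np.zeros(grid.shape)
    scatter_backproject_kernel(
        np.ascontiguousarray(stack_values, dtype=np.float64),
        grid.voxel_mm, *grid.origin_mm,
        geom.source_axis_dist_mm, geom.source_detector_dist_mm,
        geom.det_pitch_mm, geom.det_offset_mm[0], geom.det_offset_mm[1],
        np.radians(geom.angles_deg), step_mm, out,
    )
    return out
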