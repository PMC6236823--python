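"""File formats: HDF5 projection stacks, MetaImage/NIfTI volumes, text
spectra and bowtie profiles, YAML configuration and JSON metric reports.

Projection stacks travel as an HDF5 dataset ``projections`` of shape
(n_views, rows, cols) with the acquisition geometry stored as attributes;
volumes as MetaImage (.mha) or NIfTI via SimpleITK with voxel size and
origin preserved.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import SimpleITK as sitk
import yaml

from .geometry import (
    ConeBeamGeometry,
    ProjectionStack,
    VolumeImage,
    VoxelGrid,
    scaled_short_scan_geometry,
)
from .pipeline import CaliConfig
from .spectra import EnergySpectrum, default_spectrum, load_material, load_spectrum

__all__ = [
    "save_projections",
    "load_projections",
    "save_volume",
    "load_volume",
    "load_bowtie",
    "save_metrics",
    "geometry_from_dict",
    "grid_from_dict",
    "config_from_yaml",
]

_GEOM_ATTRS = ("source_axis_dist_mm", "source_detector_dist_mm", "det_pitch_mm",
               "det_offset_v_mm", "det_offset_u_mm", "angles_deg", "domain")


def save_projections(path, stack: ProjectionStack) -> None:
    g = stack.geometry
    with h5py.File(path, "w") as f:
        d = f.create_dataset("projections", data=stack.values)
        d.attrs["source_axis_dist_mm"] = g.source_axis_dist_mm
        d.attrs["source_detector_dist_mm"] = g.source_detector_dist_mm
        d.attrs["det_pitch_mm"] = g.det_pitch_mm
        d.attrs["det_offset_v_mm"] = g.det_offset_mm[0]
        d.attrs["det_offset_u_mm"] = g.det_offset_mm[1]
        d.attrs["angles_deg"] = g.angles_deg
        d.attrs["domain"] = stack.domain


def load_projections(path) -> ProjectionStack:
    with h5py.File(path, "r") as f:
        if "projections" not in f:
            raise ValueError(f"{path}: missing 'projections' dataset")
        d = f["projections"]
        for attr in _GEOM_ATTRS:
            if attr not in d.attrs:
                raise ValueError(f"{path}: missing geometry attribute '{attr}'")
        vals = d[()]
        geom = ConeBeamGeometry(
            source_axis_dist_mm=float(d.attrs["source_axis_dist_mm"]),
            source_detector_dist_mm=float(d.attrs["source_detector_dist_mm"]),
            det_rows=vals.shape[1],
            det_cols=vals.shape[2],
            det_pitch_mm=float(d.attrs["det_pitch_mm"]),
            angles_deg=np.asarray(d.attrs["angles_deg"], dtype=float),
            det_offset_mm=(float(d.attrs["det_offset_v_mm"]),
                           float(d.attrs["det_offset_u_mm"])),
        )
        domain = d.attrs["domain"]
        if isinstance(domain, bytes):
            domain = domain.decode()
        return ProjectionStack(vals, str(domain), geom)


def save_volume(path, volume: VolumeImage) -> None:
    # SimpleITK indexes (z, y, x); keep our (x, y, z) memory order by transpose
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing((volume.grid.voxel_mm,) * 3)
    origin = tuple(o + volume.grid.voxel_mm / 2 for o in volume.grid.origin_mm)
    img.SetOrigin(origin)
    img.SetMetaData("unit", volume.unit)
    sitk.WriteImage(img, str(path))


def load_volume(path, unit: str = "mm^-1") -> VolumeImage:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T
    spacing = img.GetSpacing()
    if abs(spacing[0] - spacing[1]) > 1e-9 or abs(spacing[0] - spacing[2]) > 1e-9:
        raise ValueError(f"{path}: anisotropic voxels not supported")
    vox = float(spacing[0])
    origin = tuple(o - vox / 2 for o in img.GetOrigin())
    grid = VoxelGrid(*arr.shape, vox, origin_mm=origin)
    if img.HasMetaDataKey("unit"):
        unit = img.GetMetaData("unit")
    return VolumeImage(arr, grid, unit)


def load_bowtie(path, geom: ConeBeamGeometry) -> np.ndarray:
    """Bowtie profile text file: one aluminium path length (mm) per detector
    column, or two columns (index, mm)."""
    arr = np.loadtxt(path)
    if arr.ndim == 2:
        arr = arr[:, 1]
    if arr.shape != (geom.det_cols,):
        raise ValueError(
            f"bowtie profile has {arr.size} entries, detector has "
            f"{geom.det_cols} columns")
    return arr


def save_metrics(path, metrics: dict) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")


def geometry_from_dict(d: dict) -> ConeBeamGeometry:
    return scaled_short_scan_geometry(
        n_views=int(d.get("n_views", 60)),
        span_deg=float(d.get("span_deg", 200.0)),
        det_rows=int(d.get("det_rows", 72)),
        det_cols=int(d.get("det_cols", 132)),
        det_pitch_mm=float(d.get("det_pitch_mm", 2.0)),
        source_axis_dist_mm=float(d.get("sad_mm", 500.0)),
        source_detector_dist_mm=float(d.get("sdd_mm", 800.0)),
        det_offset_mm=tuple(d.get("det_offset_mm", (0.0, 0.0))),
        start_deg=float(d.get("start_deg", 0.0)),
    )


def grid_from_dict(d: dict) -> VoxelGrid:
    return VoxelGrid(int(d.get("nx", 64)), int(d.get("ny", 64)),
                     int(d.get("nz", 32)), float(d.get("voxel_mm", 2.5)))


def config_from_yaml(path, geom: ConeBeamGeometry | None = None) -> tuple[CaliConfig, dict]:
    """Build a pipeline configuration from a YAML file.

    Returns (config, raw_dict); the raw dict also carries simulation and
    phantom blocks used by the command-line tool.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    if geom is None:
        geom = geometry_from_dict(raw.get("geometry", {}))
    grid = grid_from_dict(raw.get("grid", {}))
    spec_entry = raw.get("spectrum", "default")
    n_bins = int(raw.get("n_energy_bins", 10))
    if spec_entry == "default":
        spectrum = default_spectrum(n_bins)
    else:
        spectrum = load_spectrum(spec_entry).rebin(n_bins)
    bow = raw.get("bowtie", "none")
    if bow == "default":
        from .simulate import default_bowtie
        bowtie = default_bowtie(geom, float(raw.get("bowtie_edge_mm", 6.0)))
    elif bow in (None, "none"):
        bowtie = None
    else:
        bowtie = load_bowtie(bow, geom)
    mats = raw.get("materials", {})
    stages = raw.get("stages", {})
    tv_recon = raw.get("tv_recon", {})
    cfg = CaliConfig(
        grid=grid,
        spectrum=spectrum,
        soft_material=load_material(mats.get("soft", "water")),
        bone_material=load_material(mats.get("bone", "cortical_bone")),
        bowtie_profile=bowtie,
        enable_lfac=bool(stages.get("lfac", True)),
        enable_bhc=bool(stages.get("bhc", True)),
        enable_dac=bool(stages.get("dac", True)),
        reconstruction=str(raw.get("reconstruction", "fdk")),
        bhc_iterations=int(raw.get("bhc_iterations", 3)),
        lfac_tv_weight=float(raw.get("lfac_tv_weight", 0.35)),
        tv_recon_iterations=int(tv_recon.get("iterations", 10)),
        tv_recon_weight=float(tv_recon.get("weight", 3e-4)),
        seed=int(raw.get("seed", 0)),
    )
    return cfg, raw
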