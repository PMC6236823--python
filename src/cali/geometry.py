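"""Cone-beam acquisition geometry and the in-memory image/projection containers.

Conventions (right-handed, all positions in mm):

* the rotation axis is z, the isocenter is the origin;
* at view angle beta (degrees, counter-clockwise seen from +z) the source sits
  at ``SAD * (cos beta, sin beta, 0)`` and the flat detector is perpendicular
  to the central ray at distance SDD from the source;
* detector coordinates are u (in-plane, along ``(-sin beta, cos beta, 0)``)
  and v (axial, along +z); ``det_offset_mm = (v_offset, u_offset)`` shifts the
  detector center away from the central ray -- a large v offset realizes the
  half-cone layout where the beam covers only one side of the central plane;
* voxel (i, j, k) of a grid has its center at ``origin + (index + 0.5) * voxel``
  per axis, with the default origin centering the grid on the isocenter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConeBeamGeometry",
    "VoxelGrid",
    "ProjectionStack",
    "VolumeImage",
    "scaled_short_scan_geometry",
]


@dataclass(frozen=True)
class ConeBeamGeometry:
    source_axis_dist_mm: float
    source_detector_dist_mm: float
    det_rows: int
    det_cols: int
    det_pitch_mm: float
    angles_deg: np.ndarray
    det_offset_mm: tuple[float, float] = (0.0, 0.0)  # (row/v, col/u)

    def __post_init__(self):
        if not (self.source_detector_dist_mm > self.source_axis_dist_mm > 0):
            raise ValueError("need source_detector_dist > source_axis_dist > 0")
        if self.det_rows < 1 or self.det_cols < 1 or self.det_pitch_mm <= 0:
            raise ValueError("detector grid must be positive")
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("angles_deg must be a 1-D array")
        object.__setattr__(self, "angles_deg", a)

    @property
    def n_views(self) -> int:
        return self.angles_deg.size

    @property
    def fan_angle_deg(self) -> float:
        """Full in-plane fan angle subtended by the detector columns."""
        half = (self.det_cols - 1) / 2 * self.det_pitch_mm
        off = self.det_offset_mm[1]
        u_extreme = max(abs(-half + off), abs(half + off))
        return float(2 * np.degrees(np.arctan2(u_extreme, self.source_detector_dist_mm)))

    @property
    def span_deg(self) -> float:
        a = self.angles_deg
        if a.size < 2:
            return 0.0
        step = abs(a[1] - a[0])
        return float(abs(a[-1] - a[0]) + step)  # include the last bin width

    def u_coords_mm(self) -> np.ndarray:
        return (np.arange(self.det_cols) - (self.det_cols - 1) / 2) * self.det_pitch_mm \
            + self.det_offset_mm[1]

    def v_coords_mm(self) -> np.ndarray:
        return (np.arange(self.det_rows) - (self.det_rows - 1) / 2) * self.det_pitch_mm \
            + self.det_offset_mm[0]


@dataclass(frozen=True)
class VoxelGrid:
    nx: int
    ny: int
    nz: int
    voxel_mm: float
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1 or self.voxel_mm <= 0:
            raise ValueError("grid counts must be >= 1 and voxel size positive")
        if self.origin_mm is None:
            o = tuple(-n * self.voxel_mm / 2 for n in (self.nx, self.ny, self.nz))
            object.__setattr__(self, "origin_mm", o)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.voxel_mm

    def meshgrid(self):
        return np.meshgrid(self.centers(0), self.centers(1), self.centers(2),
                           indexing="ij")


INTENSITY = "intensity"
LINE_INTEGRAL = "line_integral"


@dataclass
class ProjectionStack:
    """Per-view detector arrays, explicitly tagged as flood-normalized
    intensities or line integrals (P = -log I)."""

    values: np.ndarray
    domain: str
    geometry: ConeBeamGeometry

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.det_rows, self.geometry.det_cols)
        if v.shape != expected:
            raise ValueError(f"projection array shape {v.shape} != geometry {expected}")
        if self.domain not in (INTENSITY, LINE_INTEGRAL):
            raise ValueError(f"unknown projection domain {self.domain!r}")
        self.values = v

    def to_line_integral(self, floor: float = 1e-9) -> "ProjectionStack":
        if self.domain == LINE_INTEGRAL:
            return self
        vals = -np.log(np.maximum(self.values, floor))
        return ProjectionStack(vals, LINE_INTEGRAL, self.geometry)

    def copy(self) -> "ProjectionStack":
        return ProjectionStack(self.values.copy(), self.domain, self.geometry)


MU_MM = "mm^-1"
HU = "HU"


@dataclass
class VolumeImage:
    """3-D image on a voxel grid, either linear attenuation (mm^-1) or HU."""

    values: np.ndarray
    grid: VoxelGrid
    unit: str = MU_MM

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != self.grid.shape:
            raise ValueError(f"volume shape {v.shape} != grid {self.grid.shape}")
        if self.unit not in (MU_MM, HU):
            raise ValueError(f"unknown volume unit {self.unit!r}")
        self.values = v

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.values.copy(), self.grid, self.unit)


def scaled_short_scan_geometry(
    n_views: int = 60,
    span_deg: float = 200.0,
    det_rows: int = 72,
    det_cols: int = 132,
    det_pitch_mm: float = 2.0,
    source_axis_dist_mm: float = 500.0,
    source_detector_dist_mm: float = 800.0,
    det_offset_mm: tuple[float, float] = (0.0, 0.0),
    start_deg: float = 0.0,
) -> ConeBeamGeometry:
    """Desk-scale short-scan geometry preserving the clinical layout's
    structure (flat panel, ~200 degree short scan, optional offset detector)
    at a fraction of the full problem size."""
    step = span_deg / n_views
    angles = start_deg + step * np.arange(n_views)
    return ConeBeamGeometry(
        source_axis_dist_mm=source_axis_dist_mm,
        source_detector_dist_mm=source_detector_dist_mm,
        det_rows=det_rows,
        det_cols=det_cols,
        det_pitch_mm=det_pitch_mm,
        angles_deg=angles,
        det_offset_mm=det_offset_mm,
    )
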