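"""Digital phantoms: a sensitometry cylinder and a cranial phantom.

The sensitometry phantom mirrors the layout of a commercial image-quality
phantom's sensitometry module -- a cylindrical acrylic shell with a
water-equivalent interior and seven cylindrical inserts of known materials
(air, PMP, LDPE, polystyrene, acrylic, Delrin, Teflon) plus small acrylic
spheres -- at desk-scale dimensions chosen so each insert spans several
voxels of the scaled reconstruction grid (24 mm inserts on a 45 mm circle
inside a 75 mm body; fixture constants, not manufacturer values).

The cranial phantom is an ellipsoidal cortical-bone skull enclosing brain
tissue with low-contrast CSF-filled ventricle lobes (~1.3% attenuation
contrast) and a thin blood vessel, optionally with four titanium frame-pin
cylinders at the skull periphery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VoxelGrid
from .metrics import ROISpec
from .spectra import MaterialTable, load_material

__all__ = [
    "LabeledPhantom",
    "InsertSpec",
    "make_catphan_sensitometry",
    "make_head_phantom",
    "SENSITOMETRY_MATERIALS",
]

SENSITOMETRY_MATERIALS = ("air", "pmp", "ldpe", "polystyrene", "acrylic",
                          "delrin", "teflon")


@dataclass(frozen=True)
class InsertSpec:
    name: str
    material: str
    label: int
    center_mm: tuple[float, float]
    radius_mm: float
    z_range_mm: tuple[float, float]

    def roi(self, grid: VoxelGrid, radius_fraction: float = 0.75) -> ROISpec:
        """ROI inside this insert (default 3/4 of the insert radius),
        restricted to the central half of the insert's z extent."""
        zc = grid.centers(2)
        z0, z1 = self.z_range_mm
        zm, zh = (z0 + z1) / 2, (z1 - z0) / 4
        idx = np.where((zc >= zm - zh) & (zc <= zm + zh))[0]
        if idx.size == 0:
            raise ValueError(f"insert {self.name} has no z coverage on grid")
        return ROISpec(self.center_mm, radius_fraction * self.radius_mm,
                       (int(idx[0]), int(idx[-1])))


@dataclass
class LabeledPhantom:
    """Integer label volume with one material per label (label 0 = air)."""

    labels: np.ndarray
    material_of_label: dict[int, MaterialTable]
    grid: VoxelGrid
    inserts: tuple[InsertSpec, ...] = ()
    background_roi: ROISpec | None = None

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.shape:
            raise ValueError("label volume shape must match grid")
        present = set(np.unique(lab).tolist())
        missing = present - set(self.material_of_label)
        if missing:
            raise ValueError(f"labels without material: {sorted(missing)}")
        self.labels = lab.astype(np.int32)

    @property
    def label_ids(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())

    def mu_volume(self, energy_keV: float) -> np.ndarray:
        """Monochromatic attenuation map (mm^-1) at one energy."""
        out = np.zeros(self.grid.shape)
        for lab in self.label_ids:
            out[self.labels == lab] = float(
                self.material_of_label[lab].mu_at(energy_keV))
        return out


def _cylinder(X, Y, Z, cx, cy, r, z0, z1):
    return ((X - cx) ** 2 + (Y - cy) ** 2 <= r**2) & (Z >= z0) & (Z <= z1)


def make_catphan_sensitometry(
    grid: VoxelGrid,
    body_radius_mm: float = 75.0,
    shell_thickness_mm: float = 5.0,
    insert_radius_mm: float = 12.0,
    insert_circle_mm: float = 45.0,
    body_half_length_mm: float = 30.0,
) -> LabeledPhantom:
    """Desk-scale digital sensitometry phantom.

    Labels: 1 acrylic shell (and acrylic spheres), 2 water interior,
    3..9 the seven sensitometry inserts in HU order
    (air < PMP < LDPE < polystyrene < acrylic < Delrin < Teflon).
    """
    half_x = grid.nx * grid.voxel_mm / 2
    half_y = grid.ny * grid.voxel_mm / 2
    if min(half_x, half_y) < body_radius_mm + 2 * grid.voxel_mm:
        raise ValueError(
            f"grid extent {2 * min(half_x, half_y):.0f} mm too small for a "
            f"{2 * body_radius_mm:.0f} mm phantom")
    X, Y, Z = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.int32)
    zl, zh = -body_half_length_mm, body_half_length_mm
    body = _cylinder(X, Y, Z, 0, 0, body_radius_mm, zl, zh)
    interior = _cylinder(X, Y, Z, 0, 0, body_radius_mm - shell_thickness_mm,
                         zl, zh)
    labels[body] = 1
    labels[interior] = 2

    materials = {0: load_material("air"), 1: load_material("acrylic"),
                 2: load_material("water")}
    inserts = []
    iz = (-body_half_length_mm + 10.0, body_half_length_mm - 10.0)
    for k, mat in enumerate(SENSITOMETRY_MATERIALS):
        ang = np.radians(90.0 + k * 360.0 / len(SENSITOMETRY_MATERIALS))
        cx = insert_circle_mm * np.cos(ang)
        cy = insert_circle_mm * np.sin(ang)
        lab = 3 + k
        labels[_cylinder(X, Y, Z, cx, cy, insert_radius_mm, iz[0], iz[1])] = lab
        materials[lab] = load_material(mat)
        inserts.append(InsertSpec(mat, mat, lab, (float(cx), float(cy)),
                                  insert_radius_mm, iz))

    # small acrylic spheres in the uniform interior (share the shell label)
    for ang_deg, r_sph in ((20.0, 5.0), (140.0, 6.0), (260.0, 7.0)):
        a = np.radians(ang_deg)
        cx, cy = 20.0 * np.cos(a), 20.0 * np.sin(a)
        sphere = (X - cx) ** 2 + (Y - cy) ** 2 + Z**2 <= r_sph**2
        labels[sphere] = 1

    # background ROI in the water interior, away from inserts and spheres
    zc = grid.centers(2)
    zi = np.where((zc >= iz[0] / 2) & (zc <= iz[1] / 2))[0]
    background = ROISpec((0.0, 0.0), 9.0, (int(zi[0]), int(zi[-1])))
    return LabeledPhantom(labels, materials, grid, tuple(inserts), background)


def make_head_phantom(grid: VoxelGrid, with_metal: bool = False) -> LabeledPhantom:
    """Ellipsoidal skull + brain phantom, optionally with titanium pins.

    Labels: 1 cortical bone skull, 2 brain, 3 CSF ventricles, 4 blood
    vessel, 5 titanium pins (only when ``with_metal``).
    """
    X, Y, Z = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.int32)

    def ellipsoid(cx, cy, cz, ax, ay, az):
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 \
            + ((Z - cz) / az) ** 2 <= 1.0

    outer = ellipsoid(0, 0, 0, 70, 55, 38)
    inner = ellipsoid(0, 0, 0, 63, 48, 32)
    labels[outer] = 1
    labels[inner] = 2
    # two ventricle lobes, low-contrast CSF
    labels[ellipsoid(-14, 6, 2, 17, 8, 10)] = 3
    labels[ellipsoid(14, 6, 2, 17, 8, 10)] = 3
    # a thin vessel running along x
    vessel = (Y - (-18.0)) ** 2 + (Z - 6.0) ** 2 <= 3.0**2
    labels[vessel & inner & (np.abs(X) < 40) & (labels == 2)] = 4

    materials = {0: load_material("air"), 1: load_material("cortical_bone"),
                 2: load_material("soft_tissue"), 3: load_material("csf"),
                 4: load_material("blood")}
    if with_metal:
        for sx, sy in ((54, 41), (-54, 41), (54, -41), (-54, -41)):
            pin = _cylinder(X, Y, Z, sx, sy, 4.0, -10.0, 10.0)
            labels[pin] = 5
        materials[5] = load_material("titanium")
    return LabeledPhantom(labels, materials, grid)
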