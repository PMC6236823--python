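"""Regenerate the packaged material attenuation tables and the default spectrum.

The packaged mass-attenuation tables are synthetic: they are computed from a
parametric photon cross-section model (exact Klein-Nishina incoherent
scattering per electron plus a single fitted a*Z^p/E^q absorption term that
lumps photoelectric and coherent contributions) evaluated over elemental mass
fractions. The three free parameters are calibrated against memorised water
and aluminium anchor values, which reproduces low-Z diagnostic-energy
attenuation to a few percent -- adequate for a simulation fixture, not a
dosimetry reference.

Run from the repository root:  python scripts/make_material_tables.py
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

OUT = Path(__file__).resolve().parents[1] / "src" / "cali" / "data"

N_A = 6.02214076e23
R_E = 2.8179403262e-13  # classical electron radius, cm
MEC2 = 510.99895  # keV

# element -> (Z, A)
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "F": (9, 18.998), "Na": (11, 22.990), "Mg": (12, 24.305),
    "Al": (13, 26.982), "P": (15, 30.974), "S": (16, 32.06),
    "Cl": (17, 35.45), "Ar": (18, 39.948), "K": (19, 39.098),
    "Ca": (20, 40.078), "Ti": (22, 47.867),
}

# material -> (density g/cm^3, {element: mass fraction})
MATERIALS = {
    "air":         (1.205e-3, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
    "water":       (1.000, {"H": 0.1119, "O": 0.8881}),
    "soft_tissue": (1.040, {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712,
                            "Na": 0.002, "P": 0.004, "S": 0.002, "Cl": 0.003,
                            "K": 0.003}),
    "csf":         (1.027, {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712,
                             "Na": 0.002, "P": 0.004, "S": 0.002, "Cl": 0.003,
                             "K": 0.003}),
    "blood":       (1.058, {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712,
                            "Na": 0.002, "P": 0.004, "S": 0.002, "Cl": 0.003,
                            "K": 0.003}),
    "cortical_bone": (1.920, {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                              "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003,
                              "Ca": 0.225}),
    "acrylic":     (1.190, {"H": 0.0805, "C": 0.5998, "O": 0.3196}),
    "polystyrene": (1.050, {"H": 0.0774, "C": 0.9226}),
    "ldpe":        (0.920, {"H": 0.1437, "C": 0.8563}),
    "pmp":         (0.830, {"H": 0.1437, "C": 0.8563}),
    "delrin":      (1.410, {"H": 0.0671, "C": 0.4000, "O": 0.5329}),
    "teflon":      (2.160, {"C": 0.2402, "F": 0.7598}),
    "aluminum":    (2.699, {"Al": 1.0}),
    "titanium":    (4.506, {"Ti": 1.0}),
}

# memorised anchor values, cm^2/g (diagnostic range)
ANCHORS = [
    ("water", 30.0, 0.3756), ("water", 40.0, 0.2683),
    ("water", 60.0, 0.2059), ("water", 80.0, 0.1837),
    ("aluminum", 30.0, 1.128), ("aluminum", 40.0, 0.5685),
    ("aluminum", 60.0, 0.2778), ("aluminum", 80.0, 0.2018),
]


def sigma_kn(E_keV):
    """Klein-Nishina total cross section per electron, cm^2."""
    k = np.asarray(E_keV, dtype=float) / MEC2
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = (1 + 3 * k) / (1 + 2 * k) ** 2
    return 2 * np.pi * R_E**2 * (t1 + t2 - t3)


def mass_atten(material, E_keV, a, p, q):
    """mu/rho in cm^2/g for the parametric model."""
    E = np.asarray(E_keV, dtype=float)
    _, comp = MATERIALS[material]
    out = np.zeros_like(E)
    for el, w in comp.items():
        Z, A = ELEMENTS[el]
        sigma = Z * sigma_kn(E) + a * Z**p / E**q
        out = out + w * (N_A / A) * sigma
    return out


def fit_model():
    def resid(theta):
        log_a, p, q = theta
        a = np.exp(log_a)
        r = []
        for mat, E, target in ANCHORS:
            r.append(np.log(mass_atten(mat, E, a, p, q)) - np.log(target))
        return r

    sol = least_squares(resid, x0=[np.log(1e-27), 4.5, 3.0])
    a, p, q = np.exp(sol.x[0]), sol.x[1], sol.x[2]
    return a, p, q


def main():
    a, p, q = fit_model()
    print(f"fitted absorption term: a={a:.6e}  Z^{p:.4f}  E^-{q:.4f}")
    for mat, E, target in ANCHORS:
        got = mass_atten(mat, E, a, p, q)
        print(f"  {mat:9s} {E:5.1f} keV: model {got:.4f} anchor {target:.4f} "
              f"({100 * (got / target - 1):+.2f}%)")

    grid = np.arange(10.0, 151.0, 5.0)
    mdir = OUT / "materials"
    mdir.mkdir(parents=True, exist_ok=True)
    for name, (rho, comp) in MATERIALS.items():
        mu_rho = mass_atten(name, grid, a, p, q)
        lines = [
            f"# synthetic mass attenuation table for {name}",
            "# generated by scripts/make_material_tables.py from a parametric",
            "# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);",
            "# approximate, for simulation fixtures only",
            f"# density_g_cm3 = {rho}",
            "# energy_keV  mu_over_rho_cm2_g",
        ]
        for E, m in zip(grid, mu_rho):
            lines.append(f"{E:.1f}  {m:.6e}")
        (mdir / f"{name}.txt").write_text("\n".join(lines) + "\n")
    print(f"wrote {len(MATERIALS)} material tables to {mdir}")

    # 90 kVp tungsten bremsstrahlung: Kramers law filtered by 8 mm Al
    sdir = OUT / "spectra"
    sdir.mkdir(parents=True, exist_ok=True)
    kvp = 90.0
    E = np.arange(16.0, kvp, 1.0)
    mu_al_mm = mass_atten("aluminum", E, a, p, q) * MATERIALS["aluminum"][0] / 10.0
    S = E * (kvp - E) * np.exp(-mu_al_mm * 8.0)
    S = S / S.max()
    lines = [
        "# synthetic 90 kVp tungsten spectrum (Kramers bremsstrahlung model,",
        "# 8 mm Al total filtration); generated by",
        "# scripts/make_material_tables.py; approximate",
        "# energy_keV  relative_fluence",
    ]
    for e, s in zip(E, S):
        lines.append(f"{e:.1f}  {s:.6e}")
    (sdir / "w90kvp.txt").write_text("\n".join(lines) + "\n")
    print(f"wrote spectrum to {sdir / 'w90kvp.txt'}")

    # quick sanity: HU ordering of the sensitometry materials at 60 keV
    order = ["air", "pmp", "ldpe", "polystyrene", "water", "acrylic",
             "delrin", "teflon"]
    mus = {m: mass_atten(m, 60.0, a, p, q)[()] * MATERIALS[m][0] for m in order}
    print(json.dumps({m: round(float(v), 5) for m, v in mus.items()}, indent=1))
    vals = [mus[m] for m in order]
    assert all(x < y for x, y in zip(vals, vals[1:])), "HU ordering violated"
    b = mass_atten("soft_tissue", 60.0, a, p, q)[()] * MATERIALS["soft_tissue"][0]
    c = mass_atten("csf", 60.0, a, p, q)[()] * MATERIALS["csf"][0]
    print(f"ventricle/brain contrast at 60 keV: {100 * (1 - c / b):.2f}%")


if __name__ == "__main__":
    main()
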