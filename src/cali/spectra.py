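"""X-ray spectrum and material attenuation bookkeeping.

Every polychromatic computation in the framework reduces to three quantities
derived from a discrete spectrum S(E) and per-material linear attenuation
curves mu(E):

* the normalized spectrum  Shat(E) = S(E) / sum_E S(E),
* the spectrum-weighted effective attenuation  mu_bar = sum_E Shat(E) mu(E)
  (the "equivalent attenuation at the mean energy" used by the corrections;
  note this is the spectral mean of mu, which in general differs slightly
  from mu evaluated at the mean energy -- the weighted-mean form is the one
  implemented throughout), and
* the per-bin ratio  sigma_hat(E) = mu(E) / mu_bar, which satisfies
  sum_E Shat(E) sigma_hat(E) = 1 by construction.

Material tables are stored as mass attenuation vs energy plus a density and
interpolated log-log, the standard choice for photon cross sections.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EnergySpectrum",
    "MaterialTable",
    "InvalidSpectrumError",
    "normalize_spectrum",
    "mean_energy",
    "effective_mu",
    "sigma_hat",
    "load_spectrum",
    "load_material",
    "default_spectrum",
    "available_materials",
]


class InvalidSpectrumError(ValueError):
    """Raised for spectra with no positive fluence or a bad energy grid."""


@dataclass(frozen=True)
class EnergySpectrum:
    """Discrete X-ray spectrum: strictly increasing bin centers (keV) and
    non-negative relative fluence per bin."""

    energies_keV: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_keV, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape or e.size == 0:
            raise InvalidSpectrumError("energies and weights must be matching 1-D arrays")
        if e.size > 1 and not np.all(np.diff(e) > 0):
            raise InvalidSpectrumError("energies must be strictly increasing")
        if np.any(w < 0) or not np.any(w > 0):
            raise InvalidSpectrumError("weights must be non-negative with at least one positive")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "weights", w)

    @property
    def n_bins(self) -> int:
        return self.energies_keV.size

    def rebin(self, n_bins: int) -> "EnergySpectrum":
        """Coarsen to ``n_bins`` groups of consecutive bins; each group keeps
        its total fluence at its fluence-weighted mean energy."""
        if n_bins >= self.n_bins:
            return self
        edges = np.linspace(0, self.n_bins, n_bins + 1).astype(int)
        energies, weights = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            w = self.weights[lo:hi]
            e = self.energies_keV[lo:hi]
            tot = w.sum()
            if tot <= 0:
                continue
            energies.append(float(np.dot(w, e) / tot))
            weights.append(float(tot))
        return EnergySpectrum(np.array(energies), np.array(weights))


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation of one material tabulated on a monotone energy grid."""

    name: str
    energies_keV: np.ndarray
    mu_linear_per_mm: np.ndarray
    density_g_cm3: float

    def __post_init__(self):
        e = np.asarray(self.energies_keV, dtype=float)
        mu = np.asarray(self.mu_linear_per_mm, dtype=float)
        if e.ndim != 1 or e.shape != mu.shape or e.size < 2:
            raise ValueError("need matching 1-D energy/attenuation arrays, >= 2 points")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(mu < 0):
            raise ValueError("attenuation must be non-negative")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "mu_linear_per_mm", mu)

    def mu_at(self, energies_keV) -> np.ndarray:
        """Linear attenuation (mm^-1) at the requested energies.

        Interpolates log(mu) linearly in log(E) between tabulated points;
        energies outside the table raise.  Zero attenuation entries (possible
        for near-vacuum materials) fall back to linear interpolation.
        """
        E = np.atleast_1d(np.asarray(energies_keV, dtype=float))
        lo, hi = self.energies_keV[0], self.energies_keV[-1]
        if np.any(E < lo - 1e-9) or np.any(E > hi + 1e-9):
            raise ValueError(
                f"energy out of range for material '{self.name}': "
                f"requested [{E.min():.3g}, {E.max():.3g}] keV, "
                f"table covers [{lo:.3g}, {hi:.3g}] keV"
            )
        E = np.clip(E, lo, hi)
        if np.all(self.mu_linear_per_mm > 0):
            out = np.exp(
                np.interp(np.log(E), np.log(self.energies_keV), np.log(self.mu_linear_per_mm))
            )
        else:  # pragma: no cover - air tables are positive in practice
            out = np.interp(E, self.energies_keV, self.mu_linear_per_mm)
        if np.isscalar(energies_keV):
            return out[0]
        return out


def normalize_spectrum(spectrum: EnergySpectrum) -> EnergySpectrum:
    """Return the spectrum with weights scaled to unit sum (Shat)."""
    total = spectrum.weights.sum()
    return EnergySpectrum(spectrum.energies_keV, spectrum.weights / total)


def mean_energy(spectrum: EnergySpectrum) -> float:
    """Fluence-weighted mean energy sum_E Shat(E)*E, in keV."""
    s = normalize_spectrum(spectrum)
    return float(np.dot(s.weights, s.energies_keV))


def effective_mu(material: MaterialTable, spectrum: EnergySpectrum) -> float:
    """Spectrum-weighted effective linear attenuation sum_E Shat(E) mu(E), mm^-1."""
    s = normalize_spectrum(spectrum)
    return float(np.dot(s.weights, material.mu_at(s.energies_keV)))


def sigma_hat(material: MaterialTable, spectrum: EnergySpectrum) -> np.ndarray:
    """Per-bin attenuation ratio sigma_hat(E) = mu(E)/mu_bar.

    Satisfies sum_E Shat(E) sigma_hat(E) = 1.  For an effectively
    non-attenuating material (mu_bar ~ 0, i.e. air/vacuum) the ratio is
    defined as 1 everywhere: its contribution to any line integral is
    negligible but the value must stay finite.
    """
    mu_bar = effective_mu(material, spectrum)
    if mu_bar <= 1e-12:
        return np.ones(spectrum.n_bins)
    s = normalize_spectrum(spectrum)
    return material.mu_at(s.energies_keV) / mu_bar


# ---------------------------------------------------------------------------
# packaged data


def _read_two_column(path_or_text) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict = {}
    rows = []
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("#").partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"line {ln}: expected two columns, got {raw!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"line {ln}: non-numeric entry in {raw!r}") from exc
    if not rows:
        raise ValueError("no data rows found")
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], meta


def load_spectrum(path) -> EnergySpectrum:
    """Load a two-column (keV, relative fluence) text spectrum."""
    e, w, _ = _read_two_column(path)
    return EnergySpectrum(e, w)


def _data_text(subdir: str, fname: str) -> str:
    ref = resources.files("cali").joinpath("data", subdir, fname)
    return ref.read_text()


def default_spectrum(n_bins: int = 10) -> EnergySpectrum:
    """Packaged synthetic 90 kVp tungsten spectrum, rebinned to ``n_bins``."""
    e, w, _ = _read_two_column(_data_text("spectra", "w90kvp.txt"))
    return normalize_spectrum(EnergySpectrum(e, w).rebin(n_bins))


def available_materials() -> list[str]:
    ref = resources.files("cali").joinpath("data", "materials")
    return sorted(p.name[:-4] for p in ref.iterdir() if p.name.endswith(".txt"))


def load_material(name_or_path) -> MaterialTable:
    """Load a material by packaged name (e.g. 'water') or from a text file.

    Files hold (keV, mu/rho in cm^2/g) columns and a '# density_g_cm3 = x'
    header; linear attenuation is mass attenuation times density, converted
    to mm^-1.
    """
    name = str(name_or_path)
    if Path(name).is_file():
        e, mu_rho, meta = _read_two_column(name)
        label = Path(name).stem
    else:
        e, mu_rho, meta = _read_two_column(_data_text("materials", f"{name}.txt"))
        label = name
    if "density_g_cm3" not in meta:
        raise ValueError(f"material file for '{label}' lacks a density_g_cm3 header")
    rho = float(meta["density_g_cm3"])
    mu_mm = mu_rho * rho / 10.0  # cm^-1 -> mm^-1
    return MaterialTable(label, e, mu_mm, rho)
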