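"""Spectrum and material bookkeeping: the quantities every polychromatic
computation is built from.

Loads the packaged 90 kVp spectrum and material tables, and prints the
effective (spectrum-weighted) attenuation, the expected CT numbers of the
sensitometry materials, and the per-bin hardening ratios sigma_hat whose
weighted sum is identically one.
"""
import numpy as np

from cali import default_spectrum, effective_mu, load_material, mean_energy, sigma_hat
from cali.spectra import normalize_spectrum

spectrum = default_spectrum(10)
print(f"90 kVp spectrum, {spectrum.n_bins} bins, "
      f"mean energy {mean_energy(spectrum):.2f} keV")

water = effective_mu(load_material("water"), spectrum)
print(f"\n{'material':14s} {'mu_bar (1/mm)':>14s} {'CT# (HU)':>10s}")
for name in ("air", "pmp", "ldpe", "polystyrene", "water", "acrylic",
             "delrin", "teflon", "cortical_bone", "titanium"):
    mu = effective_mu(load_material(name), spectrum)
    hu = 1000.0 * (mu - water) / water
    print(f"{name:14s} {mu:14.5f} {hu:10.1f}")

print("\nper-bin hardening ratio sigma_hat (mu(E)/mu_bar):")
s = normalize_spectrum(spectrum)
for name in ("water", "cortical_bone"):
    sh = sigma_hat(load_material(name), spectrum)
    print(f"{name:14s} {np.array2string(sh, precision=2)}"
          f"  (weighted sum = {np.dot(s.weights, sh):.12f})")
# sigma_hat spreads far above/below one for bone: low-energy bins attenuate
# several times more than the spectrum average, which is exactly the
# nonlinearity the beam-hardening correction models.
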