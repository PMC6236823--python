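# cali — contrast and attenuation-map linearity improvement for cone-beam CT

Flat-panel cone-beam CT (CBCT) images used for image-guided cranial
radiosurgery suffer from low-frequency shading (scatter, flood-field
saturation), beam hardening, and — on systems with a bowtie filter — a
dome/capping artifact. Together these compress and distort the
reconstructed attenuation map: CT numbers are inaccurate, their relation
to the true attenuation is non-linear, and low-contrast soft tissue
(ventricles, vessels) disappears. `cali` implements a correction framework
for this problem, together with a synthetic acquisition simulator, so every
stage is testable without scanner data.

The chain applies, in order:

* **LFAC** (low-frequency artifact correction, projection domain):
  reconstruct, segment into air/soft tissue/bone (or use a known phantom
  model), polychromatically re-project the segmentation as an ideal
  reference, TV-smooth the measured-minus-ideal difference and subtract it.
  The smooth residual is the shading estimate; structures stay untouched.
* **BHC** (iterative beam-hardening correction): map the reconstruction
  f(x) onto basis materials with the partition-of-unity weights
  `T_i = (mu_{i+1} − f)/(mu_{i+1} − mu_i) · mu_i` (and symmetrically for
  `T_{i+1}`), then update the line integrals with the mono/poly mismatch

  ```
  P_poly = −log Σ_E Ŝ(E) exp(−Σ_i σ̂_i(E) g_i),   g_i = projection of T_i
  P_{n+1} = −log I_C + P_mono − P_poly,            P_mono = Σ_i g_i
  ```

  where `Ŝ` is the normalized spectrum and `σ̂_i(E) = μ_i(E)/μ̄_i` the
  per-bin hardening ratio. Three iterations suffice.
* **DAC** (dome artifact correction, image domain): estimate each voxel's
  locally sensed mean energy by unfiltered energy-dependent backprojection
  of the post-bowtie spectrum, then remap the voxel value from the local
  basis-material nodes to the global reference spectrum.
* **MAR** (metal artifact reduction): threshold-detect metal, inpaint its
  sinogram shadow, run the chain, and restore detail through a TV-smoothed
  synthetic-image residual that protects low-contrast soft tissue.

Short-scan (Parker-weighted) FDK reconstruction, a ray-driven
mono/polychromatic projector, a TV-regularized iterative reconstruction,
digital sensitometry and cranial phantoms, and CT-number quality metrics
(linearity slope, mean absolute CT# error, CNR) are included.

## Worked example

`examples/full_correction.py` calibrates the simulator so the uncorrected
short-scan FDK of a digital sensitometry phantom has linearity slope
~0.80, then runs the full chain:

```
calibrated scatter-to-primary 0.0312: uncorrected slope 0.805, MAE 101.7 HU

insert        true HU   FDK HU  corrected HU
air            -998.9   -925.1        -954.2
pmp            -235.9   -262.9        -206.8
ldpe           -153.1   -188.5        -126.3
polystyrene     -80.1   -128.6         -57.9
acrylic          88.1      7.7          95.8
delrin          310.8    182.8         312.6
teflon         1020.7    702.2         984.3

corrected: slope 0.958, intercept 13.4 HU, MAE 24.1 HU
beam-hardening relative changes per iteration: ['0.0241', '0.0015', '0.0001']
```

The slope of measured-vs-true CT# recovers from 0.80 to 0.96, the mean
absolute CT# error falls from ~102 to ~24 HU, and the residual error is
nearly constant in true CT# (the spectral-mismatch bias of the basis
decomposition). The other examples cover spectrum/material bookkeeping,
plain simulation + FDK, and metal artifact reduction
(`examples/metal_artifact_reduction.py` prints a 61% streak reduction with
the ventricle contrast preserved at 86%).

A thin command line mirrors the library for shell use:

```
cali simulate --phantom catphan --config cfg.yaml --out proj.h5
cali run      --proj proj.h5    --config cfg.yaml --out corrected.mha
cali metrics  --vol corrected.mha --config cfg.yaml --report report.json
```

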