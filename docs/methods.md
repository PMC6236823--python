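# Methods

This note documents the models behind `cali`: what each stage assumes,
which parameters matter, what the simulator does and does not emulate, and
where the open design choices were resolved.

## Acquisition model and geometry

A circular cone-beam trajectory with a flat detector: source at
`SAD·(cos β, sin β, 0)`, detector perpendicular to the central ray at
distance SDD, detector coordinates u (in-plane) and v (axial, along the
rotation axis z). A detector offset realizes the half-cone layout of
compact cranial scanners, where the beam covers one side of the central
plane. Reconstruction uses the standard short-scan FDK chain: cosine
pre-weighting, Parker redundancy weights with smooth overscan transitions
(half-width `δ = (span − π)/2`, which must be at least the fan half-angle;
conjugate rays `(β, γ)` and `(β + π − 2γ, −γ)` receive weights summing to
one), band-limited ramp filtering per detector row, and voxel-driven
backprojection with the `SAD²/U²` distance weight. The forward projector
marches each source–pixel ray at half a voxel step with trilinear
interpolation; its exact adjoint (scatter form) backs the iterative
TV reconstruction. The ray-driven/voxel-driven pair is not an exact
adjoint pair; inner products agree to within ~2%.

Default desk-scale geometry: SAD 500 mm, SDD 800 mm, 72×132 detector at
2 mm pitch, 60 views over 200°, 64×64×32 voxels at 2.5 mm. These preserve
the structure of a clinical half-cone short scan (full-scale systems use
~780×720 detectors, 334 views, 448³ volumes) at a size where every
experiment runs in seconds to a couple of minutes on one CPU; problem
sizes are stated with each experiment.

## Spectrum and materials

All polychromatic computations reduce to the normalized spectrum `Ŝ(E)`,
the effective attenuation `μ̄ = Σ_E Ŝ(E) μ(E)` and the hardening ratio
`σ̂(E) = μ(E)/μ̄` (whose `Ŝ`-weighted sum is identically 1). Note `μ̄` is
the spectrum-weighted mean of `μ`, which differs slightly from `μ`
evaluated at the mean energy; the weighted-mean form is used consistently,
so reconstructed values after beam-hardening correction live on the
effective-attenuation scale.

The packaged data are synthetic. Mass-attenuation tables come from a
parametric photon cross-section model — exact Klein–Nishina incoherent
scattering per electron plus one fitted `a·Z^p/E^q` absorption term
calibrated to memorised water and aluminium anchors (reproduced to <1%) —
evaluated over elemental compositions; they are simulation fixtures, not
dosimetry references. The default spectrum is a 90 kVp Kramers
bremsstrahlung model behind 8 mm Al total filtration (mean energy
58.8 keV), rebinned to 10 bins. The heavy filtration is a deliberate
fixture choice: with a lightly filtered spectrum, beam hardening alone
drives the uncorrected linearity slope of the sensitometry fixture to
0.80, leaving no room for the scatter term that the shading-correction
experiments calibrate; with 8 mm Al the hardening-only slope is ~0.91 and
calibrated scatter carries the remainder, matching the premise that
shading is the dominant low-frequency error.

## Synthetic phantoms and degradations

The sensitometry phantom is a 150 mm acrylic cylinder with a
water-equivalent interior, seven 24 mm inserts (air, PMP, LDPE,
polystyrene, acrylic, Delrin, Teflon) on a 45 mm circle, and three small
acrylic spheres. The insert dimensions are enlarged relative to the
commercial module (12.2 mm on a 58.4 mm circle) because at the 2.5 mm
desk-scale voxel size the commercial inserts would span barely two voxels;
materials and ordering are unchanged. The cranial phantom is an
ellipsoidal cortical-bone skull around brain tissue with CSF ventricle
lobes at 1.25% attenuation contrast, a thin blood vessel, and optionally
four titanium pins at the skull periphery.

The degradation chain models, in order: per-column bowtie hardening
(parabolic aluminium profile, 6 mm at the widest column by default),
polychromatic Beer–Lambert primaries from per-label path lengths, additive
low-frequency scatter (Gaussian-blurred scaled primary, 80 mm FWHM, scaled
by the scatter-to-primary ratio), a smooth multiplicative flood-field
saturation error (2% central bump) that survives the ideal flood
normalization, and Poisson noise at a given fluence. With all knobs
neutral the chain is exactly the polychromatic projection of the labelled
phantom. It does **not** model Monte-Carlo scatter distributions, detector
lag/glare/energy response, or focal-spot blur — so passing tests
demonstrate that each correction removes the degradation it models, not
that the simulator reproduces any particular scanner. Calibration
searches (bisection over the scatter ratio for a target uncorrected
linearity slope, over fluence for a target CNR) pin the fixtures to a
reproducible operating point.

## Shading correction (LFAC)

The ideal reference is either a histogram segmentation of the FDK
reconstruction (clinical route) or, for phantom experiments where the
object's composition is known, the re-projection of the phantom model —
the digital analogue of using the phantom's CAD description. When the
system carries a bowtie, the reference includes it, so the difference
contains only un-modelled degradations and the dome effect is left to its
dedicated correction. Before segmentation the cone-corrupted region
(unity-volume round trip deviating by more than 30%) is TV-inpainted so
the error does not propagate through re-projection.

Segmentation takes the air/soft threshold at the valley between the two
dominant histogram peaks and the soft/bone threshold from Otsu's method,
accepted only when its between-class variance ratio exceeds 0.80 —
otherwise the tissue histogram is a shading-dominated continuum and a
single soft class is kept (without this guard, heavy scatter makes Otsu
bisect one material and the correction inverts).

The difference is smoothed per 2-D view with Chambolle ROF (weight 0.35
in line-integral units for the segmentation route, where
anatomy-mismatch structures must be flattened; 0.2 for the model-reference
route, where the difference contains only degradations and noise). ROF
shrinks a structure's amplitude by roughly `2w/r`, so small low-amplitude
detail drops out of the shading estimate while the wide scatter field
passes through. Two limitations follow directly: structures whose
amplitude×scale overlaps the scatter field cannot be separated by any
single weight (the reason the phantom experiments use the model
reference), and at coarse voxel sizes the binarized segmentation
mis-projects grazing skull rays, so the null-correction guarantee (≤1%
change on undegraded data) holds exactly on the model-reference route but
not on the segmentation route.

## Beam-hardening correction (BHC)

Basis materials are (air, soft tissue, cortical bone) for cranial data and
(air, acrylic, Teflon) for the sensitometry phantom: the middle/top basis
materials should span the object's composition, and decomposing plastics
onto cortical bone — whose `σ̂(E)` spread far exceeds any plastic's —
overshoots the predicted hardening by roughly a factor two. The mapping
clamps negative values to the first basis attenuation and caps values
above the last. Three iterations are the default; the relative projection
change falls below 1% by the second or third iteration on all fixtures.
The mono/poly mismatch norm legitimately *grows* on the first update
(the initial hardened reconstruction underestimates the line integrals),
so the divergence guard only stops the iteration when the mismatch keeps
growing by more than 25% after that. A residual near-constant CT# offset
(~15–25 HU on the plastics fixture) remains: it is the spectral mismatch
between each material's true `σ̂(E)` and that of its basis decomposition,
and is constant enough in true CT# that renormalization would remove it.

## Dome correction (DAC)

Per-voxel sensed mean energy comes from unfiltered, FDK-weighted
backprojection of the post-bowtie per-column mean energies, normalized by
backprojected unit weights; object self-filtration is deliberately
excluded (that hardening is BHC's job). Because reconstructed values live
on the effective-attenuation scale, the remapping nodes are the basis
materials' *effective* attenuations under the locally hardened spectrum,
tabulated by sweeping the bowtie thickness and indexed by mean energy; the
reference nodes are those of the unfiltered spectrum, making the
correction exactly the identity when no bowtie is present. The correction
is monotone in the input value. It is also intrinsically partial: the
ramp filter turns peripheral hardening into a central bias carried by
rays that never cross the center, which no per-voxel energy model can
represent — on the raw FDK of the bowtie fixture DAC removes ~70% of the
center-vs-periphery bias, and a residual ring/dome after the full chain is
expected behaviour.

## Metal artifact reduction (MAR)

Metal is detected at 3× the bone attenuation at the reference energy —
safely above tissue yet below even heavily beam-hardened titanium
reconstructions (the effective attenuation of Ti is never reached in the
image; thresholding at multiples of *effective* bone attenuation detects
nothing) — with sub-10-voxel components discarded and a two-voxel dilation
to capture partial-volume pin boundaries. The sinogram shadow is inpainted
per view (row-wise linear interpolation refined by TV sweeps; unmasked
pixels are bit-exact), the full chain runs on the inpainted projections,
and a synthetic image (corrected volume with soft tissue flattened to its
mean, other structures kept, detected metal restored) is re-projected.
The TV-smoothed residual of the non-inpainted shading-corrected
projections against the synthetic image is added back to the inpainted
shading-corrected projections; the remaining pipeline stages then run so
the output is directly comparable to a metal-free pipeline product, and
detected metal voxels are reinserted. Without detected metal the workflow
returns the plain pipeline result. On the cranial fixture the streak
metric (std of a brain ROI on the pin-pair axis) drops by ~60% while the
ventricle contrast stays within ~15% of the metal-free run.

## Numerical choices and conventions

* CT numbers: `HU = 1000 (μ − μ_water)/μ_water` with the spectrum-weighted
  water attenuation as reference; "true" insert CT# uses the same
  convention, and the reference energy is recorded in every metrics report.
* CNR: `(mean_signal − mean_background)/std_background`, signal ROI at 3/4
  of the insert radius.
* TV reconstruction: proximal-gradient on the least-squares data term with
  a Chambolle TV prox (weight 3·10⁻⁴ mm⁻¹, 10 iterations), warm-started
  from FDK, step size from power iteration on the exact adjoint pair, with
  a non-negativity projection.
* Degenerate inputs raise: all-zero spectra, unimodal histograms,
  non-increasing basis attenuations, fully masked views/volumes,
  insufficient angular span (error names the required span).
* Determinism: one seeded generator per simulation; pipelines are
  bit-reproducible given configuration and seed, and a configuration hash
  is recorded with every result.

## Known limitations

* The corrections share the simulator's physics (same projector, same
  spectrum model); results show internal consistency of the method chain,
  not scanner-level validation.
* The basis decomposition's spectral-mismatch offset is irreducible within
  the three-material model.
* DAC corrects only the per-voxel representable part of the dome
  (~70% single-stage, less after BHC interaction).
* The segmentation route degrades at coarse voxel sizes (partial-volume
  binarization) and under extreme shading (guarded, falling back to a
  single soft class).
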