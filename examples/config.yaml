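# Desk-scale configuration for the `cali` command line.
# Geometry: 200-degree short scan, flat panel, centered detector.
geometry:
  n_views: 60
  span_deg: 200.0
  det_rows: 72
  det_cols: 132
  det_pitch_mm: 2.0
  sad_mm: 500.0
  sdd_mm: 800.0
  det_offset_mm: [0.0, 0.0]

grid:
  nx: 64
  ny: 64
  nz: 32
  voxel_mm: 2.5

spectrum: default          # packaged synthetic 90 kVp table, or a file path
n_energy_bins: 10
bowtie: default            # parabolic aluminium profile; none | default | path
bowtie_edge_mm: 6.0

# basis materials for beam-hardening and dome correction
materials:
  soft: acrylic            # use soft_tissue / cortical_bone for cranial data
  bone: teflon

stages:
  lfac: true
  bhc: true
  dac: true
reconstruction: fdk        # fdk | tv
bhc_iterations: 3
lfac_tv_weight: 0.35

# degradation block used by `cali simulate`
degradation:
  spr: 0.03                # scatter-to-primary scaling of the blurred primary
  fwhm_mm: 80.0
  flood_amplitude: 0.02
  photons: 0               # 0 disables Poisson noise

seed: 0
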