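"""Metal artifact reduction on a cranial phantom with titanium frame pins.

Simulates the same acquisition with and without pins, runs the sinogram-
inpainting MAR workflow around the correction pipeline, and prints the
streak metric (standard deviation of a brain region on the pin-pair axis)
and the preservation of the low-contrast ventricles.
"""
from cali import VoxelGrid, default_spectrum, scaled_short_scan_geometry
from cali.fdk import fdk_reconstruct
from cali.mar import run_mar
from cali.metrics import ROISpec, roi_stats
from cali.phantoms import make_head_phantom
from cali.pipeline import CaliConfig, run_cali
from cali.simulate import (
    DegradationModel,
    default_bowtie,
    default_flood_error,
    simulate_acquisition,
)
from cali.spectra import load_material

geom = scaled_short_scan_geometry()
grid = VoxelGrid(64, 64, 32, 2.5)
spectrum = default_spectrum(10)
with_pins = make_head_phantom(grid, with_metal=True)
no_pins = make_head_phantom(grid, with_metal=False)
model = DegradationModel(scatter_to_primary=0.02,
                         bowtie_profile=default_bowtie(geom, 6.0),
                         flood_saturation_error=default_flood_error(geom, 0.02))
config = CaliConfig(grid=grid, spectrum=spectrum,
                    soft_material=load_material("soft_tissue"),
                    bone_material=load_material("cortical_bone"),
                    bowtie_profile=model.bowtie_profile)

stack = simulate_acquisition(with_pins, geom, spectrum, model)
uncorrected = fdk_reconstruct(stack.to_line_integral(), grid)
corrected = run_mar(stack, config)
reference = run_cali(simulate_acquisition(no_pins, geom, spectrum, model),
                     config).volume

roi = ROISpec((0.0, -36.0), 8.0, (14, 17))  # brain, on the lower pin axis
s_unc = roi_stats(uncorrected, roi)[1]
s_mar = roi_stats(corrected, roi)[1]
print(f"streak metric: uncorrected FDK {s_unc:.5f} /mm, "
      f"after MAR {s_mar:.5f} /mm "
      f"({100 * (1 - s_mar / s_unc):.0f}% reduction)")

vent = no_pins.labels == 3
brain = no_pins.labels == 2
c_ref = reference.values[vent].mean() - reference.values[brain].mean()
c_mar = corrected.values[vent].mean() - corrected.values[brain].mean()
print(f"ventricle-brain contrast: metal-free {c_ref:.2e}, "
      f"MAR {c_mar:.2e} /mm (ratio {c_mar / c_ref:.2f})")
# the pin streaks collapse while the ~1% ventricle contrast survives: the
# synthetic-image residual protects low-contrast soft tissue.
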