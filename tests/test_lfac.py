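import numpy as np
import pytest

from cali import EnergySpectrum, VolumeImage, VoxelGrid
from cali.fdk import fdk_reconstruct
from cali.geometry import LINE_INTEGRAL, ProjectionStack
from cali.lfac import (
    AIR,
    BONE,
    SOFT,
    SegmentationError,
    SegmentationMap,
    ideal_projections,
    inpaint_cone_region,
    lfac_correct,
    reference_projections,
    run_lfac,
    segment_by_histogram,
)
from cali.projector import forward_project_values
from cali.simulate import DegradationModel, simulate_acquisition
from cali.spectra import MaterialTable, effective_mu, load_material


class TestSegmentation:
    def test_three_plateaus_recovered_exactly(self, small_grid):
        rng = np.random.default_rng(0)
        vals = np.zeros(small_grid.shape)
        vals[10:20] = 0.02
        vals[20:] = 0.04
        vals += rng.normal(0, 2e-4, vals.shape)
        seg = segment_by_histogram(VolumeImage(vals, small_grid))
        assert np.all(seg.labels[:10] == AIR)
        assert np.all(seg.labels[10:20] == SOFT)
        assert np.all(seg.labels[20:] == BONE)

    def test_all_air_volume_raises(self, small_grid):
        vals = np.random.default_rng(1).normal(0, 1e-5, small_grid.shape)
        with pytest.raises(SegmentationError):
            segment_by_histogram(VolumeImage(vals, small_grid))

    def test_head_reconstruction_bone_dice(self, head, geom, grid, spectrum):
        stack = simulate_acquisition(head, geom, spectrum, DegradationModel())
        vol = fdk_reconstruct(stack.to_line_integral(), grid)
        seg = segment_by_histogram(vol)
        bone_true = head.labels == 1
        bone_seg = seg.labels == BONE
        dice = 2 * (bone_true & bone_seg).sum() / (bone_true.sum()
                                                   + bone_seg.sum())
        assert dice >= 0.9

    def test_shading_continuum_keeps_single_soft_class(self, small_grid):
        # a smooth gradient with an air floor must not be split into
        # soft + bone by Otsu
        x = np.linspace(0, 1, small_grid.nx)[:, None, None]
        vals = 0.015 + 0.01 * x * np.ones(small_grid.shape)
        vals[:4] = 0.0
        seg = segment_by_histogram(VolumeImage(vals, small_grid))
        assert not (seg.labels == BONE).any()


class TestIdealProjections:
    def test_air_only_segmentation_gives_zeros(self, small_geom, small_grid,
                                               spectrum):
        seg = SegmentationMap(np.zeros(small_grid.shape, dtype=np.int8),
                              (0.01, 0.03), small_grid)
        p = ideal_projections(seg, spectrum, {}, small_geom)
        assert np.all(p.values == 0)

    def test_single_material_mono_collapse(self, small_geom, small_grid):
        labels = np.zeros(small_grid.shape, dtype=np.int8)
        labels[8:24, 8:24, 4:12] = SOFT
        seg = SegmentationMap(labels, (0.01, 0.03), small_grid)
        mat = MaterialTable("flat", np.array([40.0, 80.0]),
                            np.array([0.02, 0.02]), 1.0)
        s = EnergySpectrum(np.array([60.0]), np.array([1.0]))
        p = ideal_projections(seg, s, {SOFT: mat}, small_geom)
        expected = forward_project_values(
            (labels == SOFT) * 0.02, small_grid, small_geom)
        assert np.allclose(p.values, expected, atol=1e-10)

    def test_unmapped_class_raises(self, small_geom, small_grid, spectrum):
        labels = np.full(small_grid.shape, BONE, dtype=np.int8)
        seg = SegmentationMap(labels, (0.01, 0.03), small_grid)
        with pytest.raises(ValueError, match="class"):
            ideal_projections(seg, spectrum, {SOFT: load_material("water")},
                              small_geom)

    def test_reference_closure_with_simulator(self, head, geom, spectrum):
        """Model re-projection of the true labels reproduces the simulator's
        clean projections."""
        stack = simulate_acquisition(head, geom, spectrum, DegradationModel())
        ref = reference_projections(head, spectrum, geom)
        diff = np.abs(ref.values - stack.to_line_integral().values)
        assert diff.max() < 1e-3


class TestLfacCorrect:
    def _stack(self, geom, vals):
        return ProjectionStack(vals, LINE_INTEGRAL, geom)

    def test_identity_when_measured_equals_ideal(self, small_geom):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 2, (small_geom.n_views, small_geom.det_rows,
                               small_geom.det_cols))
        out = lfac_correct(self._stack(small_geom, v),
                           self._stack(small_geom, v.copy()))
        assert np.allclose(out.values, v, atol=1e-12)

    def test_smooth_bias_field_removed(self, small_geom):
        rng = np.random.default_rng(1)
        ideal = rng.uniform(0.5, 1.5, (small_geom.n_views,
                                       small_geom.det_rows,
                                       small_geom.det_cols))
        r = np.arange(small_geom.det_rows)[:, None] / small_geom.det_rows
        c = np.arange(small_geom.det_cols)[None, :] / small_geom.det_cols
        bias = 0.8 * np.exp(-((r - 0.5) ** 2 + (c - 0.5) ** 2) / 0.18)
        measured = ideal + bias[None]
        out = lfac_correct(self._stack(small_geom, measured),
                           self._stack(small_geom, ideal), tv_weight=0.35)
        resid = out.values - ideal
        assert np.abs(resid).mean() < 0.02 * np.abs(measured).mean()

    def test_sharp_structure_survives_correction(self, small_geom):
        ideal = np.ones((small_geom.n_views, small_geom.det_rows,
                         small_geom.det_cols))
        measured = ideal.copy()
        # small low-amplitude structure (TV flattens it out of the
        # smoothed difference, so the correction leaves it untouched)
        measured[:, 15:20, 30:34] += 0.12
        out = lfac_correct(self._stack(small_geom, measured),
                           self._stack(small_geom, ideal), tv_weight=0.35)
        kept = out.values[:, 15:20, 30:34].mean() - 1.0
        assert kept > 0.08  # most of the 0.12 amplitude survives

    def test_shape_mismatch_rejected(self, small_geom, geom):
        a = np.zeros((small_geom.n_views, small_geom.det_rows,
                      small_geom.det_cols))
        b = np.zeros((geom.n_views, geom.det_rows, geom.det_cols))
        with pytest.raises(ValueError):
            lfac_correct(self._stack(small_geom, a), self._stack(geom, b))


class TestInpaint:
    def test_empty_mask_is_identity(self, small_grid):
        rng = np.random.default_rng(0)
        vol = VolumeImage(rng.uniform(0, 1, small_grid.shape), small_grid)
        out = inpaint_cone_region(vol, np.zeros(small_grid.shape, dtype=bool))
        assert np.array_equal(out.values, vol.values)

    def test_constant_volume_recovered_exactly(self, small_grid):
        vol = VolumeImage(np.full(small_grid.shape, 0.7), small_grid)
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[10:16, 10:16, 4:8] = True
        out = inpaint_cone_region(vol, mask)
        assert np.allclose(out.values, 0.7, atol=1e-9)

    def test_linear_ramp_filled_within_5pct(self):
        from cali.tv import tv_inpaint
        x = np.linspace(1.0, 2.0, 64)
        ramp = np.tile(x, (64, 1))
        mask = np.zeros_like(ramp, dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(yy - 32) ** 2 + (xx - 32) ** 2 <= 36] = True
        out = tv_inpaint(ramp, mask)
        assert np.allclose(out[mask], ramp[mask], rtol=0.05)
        assert np.array_equal(out[~mask], ramp[~mask])

    def test_full_mask_rejected(self, small_grid):
        vol = VolumeImage(np.ones(small_grid.shape), small_grid)
        with pytest.raises(ValueError, match="fully masked"):
            inpaint_cone_region(vol, np.ones(small_grid.shape, dtype=bool))


class TestRunLfac:
    def test_output_domain_is_line_integral(self, catphan, geom, grid,
                                            spectrum, catphan_paths):
        stack = simulate_acquisition(catphan, geom, spectrum,
                                     DegradationModel(), catphan_paths)
        out = run_lfac(stack, spectrum,
                       {SOFT: load_material("water"),
                        BONE: load_material("teflon")},
                       grid, reference=catphan)
        assert out.domain == LINE_INTEGRAL

    def test_degraded_catphan_improves_rms_error(self, catphan, geom, grid,
                                                 spectrum, catphan_paths):
        """Shading correction must reduce the reconstruction error of a
        scatter-degraded acquisition (segmentation route, three seeds)."""
        mu_truth = np.zeros(grid.shape)
        for lab in catphan.label_ids:
            mu_truth[catphan.labels == lab] = effective_mu(
                catphan.material_of_label[lab], spectrum)
        mats = {SOFT: load_material("water"), BONE: load_material("teflon")}
        for seed in (0, 1, 2):
            model = DegradationModel(scatter_to_primary=0.3,
                                     photons_per_pixel=1e5, seed=seed)
            stack = simulate_acquisition(catphan, geom, spectrum, model,
                                         catphan_paths)
            vu = fdk_reconstruct(stack.to_line_integral(), grid)
            corrected = run_lfac(stack, spectrum, mats, grid)
            vc = fdk_reconstruct(corrected, grid)
            e_u = np.sqrt(((vu.values - mu_truth) ** 2).mean())
            e_c = np.sqrt(((vc.values - mu_truth) ** 2).mean())
            assert e_c < e_u
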