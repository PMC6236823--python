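import numpy as np
import pytest

from cali import EnergySpectrum, VoxelGrid
from cali.geometry import INTENSITY
from cali.phantoms import (
    SENSITOMETRY_MATERIALS,
    make_catphan_sensitometry,
    make_head_phantom,
)
from cali.projector import forward_project_values
from cali.simulate import (
    DegradationModel,
    compute_path_lengths,
    default_bowtie,
    default_flood_error,
    simulate_acquisition,
)
from cali.spectra import effective_mu, load_material


class TestCatphan:
    def test_label_inventory(self, catphan):
        labs = catphan.label_ids
        assert labs == list(range(10))  # air + shell + interior + 7 inserts
        assert len(catphan.inserts) == 7
        assert [i.material for i in catphan.inserts] == list(SENSITOMETRY_MATERIALS)

    def test_insert_volumes_match_analytic_cylinders(self, catphan, grid):
        for ins in catphan.inserts:
            n = (catphan.labels == ins.label).sum()
            height = ins.z_range_mm[1] - ins.z_range_mm[0]
            analytic = np.pi * ins.radius_mm**2 * height / grid.voxel_mm**3
            # one voxel shell of tolerance around the cylinder surface
            shell = (2 * np.pi * ins.radius_mm * height
                     + 2 * np.pi * ins.radius_mm**2) / grid.voxel_mm**2
            assert abs(n - analytic) < shell

    def test_true_attenuation_ordering(self, catphan, spectrum):
        mus = [effective_mu(catphan.material_of_label[i.label], spectrum)
               for i in catphan.inserts]
        water = effective_mu(load_material("water"), spectrum)
        assert all(a < b for a, b in zip(mus, mus[1:]))
        # water sits between polystyrene and acrylic
        assert mus[2] < water < mus[4]

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            make_catphan_sensitometry(VoxelGrid(16, 16, 8, 2.5))


class TestHeadPhantom:
    def test_metal_flag(self, head, head_metal):
        assert 5 not in head.label_ids
        assert 5 in head_metal.label_ids

    def test_pins_outside_brain(self, head_metal):
        pins = head_metal.labels == 5
        head_no_metal = make_head_phantom(head_metal.grid, with_metal=False)
        brain = head_no_metal.labels >= 2
        assert not (pins & brain).any()

    def test_ventricle_contrast_is_low(self, head, spectrum):
        mu_b = effective_mu(head.material_of_label[2], spectrum)
        mu_v = effective_mu(head.material_of_label[3], spectrum)
        assert 0 < (mu_b - mu_v) / mu_b <= 0.015


class TestSimulateAcquisition:
    def test_degenerate_chain_is_identity(self, catphan, geom, catphan_paths):
        """Monoenergetic, degradation-free: -log(I) equals the mono forward
        projection of the attenuation map."""
        s = EnergySpectrum(np.array([60.0]), np.array([1.0]))
        stack = simulate_acquisition(catphan, geom, s, DegradationModel(),
                                     catphan_paths)
        assert stack.domain == INTENSITY
        mu_map = catphan.mu_volume(60.0)
        expected = forward_project_values(mu_map, catphan.grid, geom)
        assert np.allclose(stack.to_line_integral().values, expected,
                           atol=1e-6)

    def test_polychromatic_neutral_chain_matches_reference(
            self, catphan, geom, spectrum, catphan_paths):
        from cali.lfac import reference_projections
        stack = simulate_acquisition(catphan, geom, spectrum,
                                     DegradationModel(), catphan_paths)
        ref = reference_projections(catphan, spectrum, geom)
        assert np.allclose(stack.to_line_integral().values, ref.values,
                           atol=1e-9)

    def test_scatter_strictly_increases_intensity(self, catphan, geom,
                                                  spectrum, catphan_paths):
        clean = simulate_acquisition(catphan, geom, spectrum,
                                     DegradationModel(), catphan_paths)
        scat = simulate_acquisition(
            catphan, geom, spectrum,
            DegradationModel(scatter_to_primary=0.3), catphan_paths)
        assert np.all(scat.values > clean.values)

    def test_flood_error_persists_after_normalization(self, catphan, geom,
                                                      spectrum, catphan_paths):
        err = default_flood_error(geom, 0.05)
        clean = simulate_acquisition(catphan, geom, spectrum,
                                     DegradationModel(), catphan_paths)
        flood = simulate_acquisition(
            catphan, geom, spectrum,
            DegradationModel(flood_saturation_error=err), catphan_paths)
        assert np.allclose(flood.values, clean.values * err[None], rtol=1e-12)

    def test_fixed_seed_is_bit_reproducible(self, catphan, geom, spectrum,
                                            catphan_paths):
        model = DegradationModel(scatter_to_primary=0.1,
                                 photons_per_pixel=1e4, seed=7)
        a = simulate_acquisition(catphan, geom, spectrum, model, catphan_paths)
        b = simulate_acquisition(catphan, geom, spectrum, model, catphan_paths)
        assert np.array_equal(a.values, b.values)
        c = simulate_acquisition(
            catphan, geom, spectrum,
            DegradationModel(scatter_to_primary=0.1, photons_per_pixel=1e4,
                             seed=8), catphan_paths)
        assert not np.array_equal(a.values, c.values)

    def test_poisson_variance_matches_mean(self):
        """Empirical relative variance of the Poisson stage at N >= 1e4."""
        grid = VoxelGrid(4, 4, 4, 10.0)
        from cali.phantoms import LabeledPhantom
        labels = np.zeros(grid.shape, dtype=np.int32)
        ph = LabeledPhantom(labels, {0: load_material("air")}, grid)
        from cali import scaled_short_scan_geometry
        geom1 = scaled_short_scan_geometry(n_views=1, det_rows=2, det_cols=12,
                                           det_pitch_mm=4.0)
        s = EnergySpectrum(np.array([60.0]), np.array([1.0]))
        n_photons = 1e4
        draws = []
        for seed in range(300):
            st = simulate_acquisition(
                ph, geom1, s,
                DegradationModel(photons_per_pixel=n_photons, seed=seed))
            draws.append(st.values[0, 0, 0])
        draws = np.array(draws) * n_photons  # back to counts
        assert draws.var() == pytest.approx(draws.mean(), rel=0.10)

    def test_bowtie_profile_shape_checked(self, catphan, geom, spectrum):
        with pytest.raises(ValueError, match="bowtie"):
            simulate_acquisition(
                catphan, geom, spectrum,
                DegradationModel(bowtie_profile=np.zeros(3)))

    def test_degradation_model_validation(self):
        with pytest.raises(ValueError):
            DegradationModel(scatter_to_primary=-0.1)
        with pytest.raises(ValueError):
            DegradationModel(flood_saturation_error=np.zeros((2, 2)))


class TestCalibration:
    def test_scatter_monotonically_degrades_slope(self, catphan, geom,
                                                  spectrum, catphan_paths):
        from cali.simulate import uncorrected_catphan_metrics
        slopes = []
        for spr in (0.0, 0.05):
            model = DegradationModel(scatter_to_primary=spr)
            s, _, _, _ = uncorrected_catphan_metrics(
                catphan, geom, spectrum, model, catphan_paths)
            slopes.append(s)
        assert slopes[1] < slopes[0]
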