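import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cali import EnergySpectrum, VolumeImage, VoxelGrid
from cali.bhc import bhc_iterate, map_to_basis
from cali.dac import basis_node_curves, dac_correct
from cali.fdk import fdk_reconstruct
from cali.geometry import LINE_INTEGRAL, ProjectionStack
from cali.metrics import ROISpec, roi_stats
from cali.phantoms import LabeledPhantom
from cali.simulate import DegradationModel, simulate_acquisition
from cali.spectra import effective_mu, load_material, mean_energy

BASIS = (0.0, 0.02, 0.04)


class TestMapToBasis:
    def test_node_value_maps_to_single_material(self):
        d = map_to_basis(np.array([0.02]), BASIS)
        assert d.contributions[0][0] == pytest.approx(0.0, abs=1e-15)
        assert d.contributions[1][0] == pytest.approx(0.02, abs=1e-15)
        assert d.contributions[2][0] == pytest.approx(0.0, abs=1e-15)

    def test_midpoint_partitions_between_neighbours(self):
        d = map_to_basis(np.array([0.03]), BASIS)
        assert d.contributions[1][0] == pytest.approx(0.01, abs=1e-15)
        assert d.contributions[2][0] == pytest.approx(0.02, abs=1e-15)

    def test_values_above_top_material_are_capped(self):
        d = map_to_basis(np.array([0.05]), BASIS)
        assert d.contributions[2][0] == pytest.approx(0.04, abs=1e-15)
        assert sum(c[0] for c in d.contributions) == pytest.approx(0.04)

    def test_negative_values_clamp_to_first_material(self):
        d = map_to_basis(np.array([-0.01]), BASIS)
        assert sum(c[0] for c in d.contributions) == pytest.approx(0.0,
                                                                   abs=1e-15)

    def test_non_increasing_basis_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            map_to_basis(np.array([0.01]), (0.0, 0.04, 0.02))

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(f=st.floats(0.0, 0.04))
    def test_partition_of_unity_inside_range(self, f):
        """sum_i T_i(f) = f exactly for f inside [mu_1, mu_M]."""
        d = map_to_basis(np.array([f]), BASIS)
        total = sum(c[0] for c in d.contributions)
        assert total == pytest.approx(f, abs=1e-12)


@pytest.fixture(scope="module")
def water_cylinder(grid):
    X, Y, Z = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[(X**2 + Y**2 <= 65**2) & (np.abs(Z) <= 30)] = 1
    return LabeledPhantom(labels, {0: load_material("air"),
                                   1: load_material("water")}, grid)


class TestBhcIterate:
    def test_monoenergetic_spectrum_is_identity(self, water_cylinder, geom,
                                                grid):
        s = EnergySpectrum(np.array([60.0]), np.array([1.0]))
        stack = simulate_acquisition(water_cylinder, geom, s,
                                     DegradationModel())
        P = stack.to_line_integral()
        res = bhc_iterate(P, s,
                          [load_material("air"), load_material("water"),
                           load_material("cortical_bone")], grid, n_iter=2)
        assert np.allclose(res.projections.values, P.values, atol=1e-9)

    def test_water_cylinder_cupping_reduced(self, water_cylinder, geom, grid,
                                            spectrum):
        """Beam-hardening cupping (edge-minus-center bias) removed by >= 80%
        after three iterations."""
        stack = simulate_acquisition(water_cylinder, geom, spectrum,
                                     DegradationModel())
        P = stack.to_line_integral()
        v0 = fdk_reconstruct(P, grid)
        res = bhc_iterate(P, spectrum,
                          [load_material("air"), load_material("water"),
                           load_material("cortical_bone")], grid, n_iter=3)
        center = ROISpec((0.0, 0.0), 8.0, (13, 18))
        edge = ROISpec((0.0, 55.0), 6.0, (13, 18))

        def cup(v):
            return roi_stats(v, edge)[0] - roi_stats(v, center)[0]

        assert abs(cup(res.volume)) <= 0.2 * abs(cup(v0))

    def test_requires_line_integrals_and_ordered_basis(self, geom, grid,
                                                      spectrum):
        vals = np.zeros((geom.n_views, geom.det_rows, geom.det_cols))
        stack = ProjectionStack(vals + 0.5, "intensity", geom)
        with pytest.raises(ValueError, match="line-integral"):
            bhc_iterate(stack, spectrum, [load_material("air"),
                                          load_material("water"),
                                          load_material("cortical_bone")],
                        grid)
        P = ProjectionStack(vals, LINE_INTEGRAL, geom)
        with pytest.raises(ValueError, match="increasing"):
            bhc_iterate(P, spectrum, [load_material("water"),
                                      load_material("water"),
                                      load_material("cortical_bone")], grid)


class TestDacCorrect:
    @pytest.fixture(scope="class")
    def basis(self):
        return [load_material("air"), load_material("water"),
                load_material("cortical_bone")]

    def test_identity_at_reference_energy(self, small_grid, spectrum, basis):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.0, 0.05, small_grid.shape)
        vol = VolumeImage(vals, small_grid)
        emap = np.full(small_grid.shape, mean_energy(spectrum))
        out = dac_correct(vol, emap, basis, spectrum)
        inside = (vals >= effective_mu(basis[0], spectrum)) \
            & (vals <= effective_mu(basis[-1], spectrum))
        assert np.allclose(out.values[inside], vals[inside], atol=1e-7)

    def test_local_node_maps_to_reference_node(self, small_grid, spectrum,
                                               basis):
        energies, nodes = basis_node_curves(spectrum, basis)
        e_local = energies[10]
        vol = VolumeImage(np.full(small_grid.shape, nodes[1, 10]), small_grid)
        emap = np.full(small_grid.shape, e_local)
        out = dac_correct(vol, emap, basis, spectrum)
        assert np.allclose(out.values, effective_mu(basis[1], spectrum),
                           atol=1e-9)

    def test_monotone_in_input_value(self, small_grid, spectrum, basis):
        energies, _ = basis_node_curves(spectrum, basis)
        emap = np.full(small_grid.shape, energies[5])
        f = np.linspace(0, 0.06, small_grid.nx)[:, None, None] \
            * np.ones(small_grid.shape)
        out = dac_correct(VolumeImage(f, small_grid), emap, basis, spectrum)
        profile = out.values[:, 0, 0]
        assert np.all(np.diff(profile) >= -1e-12)

    def test_energy_outside_attainable_range_rejected(self, small_grid,
                                                      spectrum, basis):
        vol = VolumeImage(np.zeros(small_grid.shape), small_grid)
        emap = np.full(small_grid.shape, 150.0)
        with pytest.raises(ValueError, match="attainable"):
            dac_correct(vol, emap, basis, spectrum)
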