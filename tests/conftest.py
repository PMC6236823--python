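"""Shared fixtures: desk-scale geometry, phantoms and cached projections.

Session scope keeps the expensive pieces (per-label path lengths, numba
warm-up) to one computation for the whole suite.
"""
import numpy as np
import pytest

from cali import VoxelGrid, default_spectrum, scaled_short_scan_geometry
from cali.phantoms import make_catphan_sensitometry, make_head_phantom
from cali.simulate import compute_path_lengths


@pytest.fixture(scope="session")
def geom():
    return scaled_short_scan_geometry()


@pytest.fixture(scope="session")
def grid():
    return VoxelGrid(64, 64, 32, 2.5)


@pytest.fixture(scope="session")
def small_geom():
    # fewer views and coarser detector for cheap unit tests
    return scaled_short_scan_geometry(n_views=40, det_rows=36, det_cols=66,
                                      det_pitch_mm=4.0)


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid(32, 32, 16, 5.0)


@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum(10)


@pytest.fixture(scope="session")
def catphan(grid):
    return make_catphan_sensitometry(grid)


@pytest.fixture(scope="session")
def head(grid):
    return make_head_phantom(grid)


@pytest.fixture(scope="session")
def head_metal(grid):
    return make_head_phantom(grid, with_metal=True)


@pytest.fixture(scope="session")
def catphan_paths(catphan, geom):
    return compute_path_lengths(catphan, geom)
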