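"""Shared fixtures: GA parameter sets for short/long cell files."""

import dataclasses

import numpy as np
import pytest

import cellfile as cf


@pytest.fixture(scope="session")
def ga_phys():
    """Wild-type GA physiology (dimensional primaries)."""
    return cf.HormonePhysiology(**cf.PRESETS["ga_short"]["physiology"])


@pytest.fixture(scope="session")
def ga_phys_no_plas(ga_phys):
    return dataclasses.replace(ga_phys, P_plas=0.0)


@pytest.fixture(scope="session")
def short_geom():
    return cf.CellFileGeometry.uniform(
        n_cells=20, length_um=20.0, width_um=10.0, apoplast_um=0.5, phi=0.1
    )


@pytest.fixture(scope="session")
def long_geom():
    return cf.CellFileGeometry.uniform(
        n_cells=20, length_um=200.0, width_um=10.0, apoplast_um=0.5, phi=0.91
    )


@pytest.fixture(scope="session")
def short_params(ga_phys, short_geom):
    return cf.nondimensionalize(ga_phys, short_geom)


@pytest.fixture(scope="session")
def short_params_no_plas(ga_phys_no_plas, short_geom):
    return cf.nondimensionalize(ga_phys_no_plas, short_geom)


@pytest.fixture(scope="session")
def long_params(ga_phys, long_geom):
    return cf.nondimensionalize(ga_phys, long_geom)


@pytest.fixture(scope="session")
def long_params_no_plas(ga_phys_no_plas, long_geom):
    return cf.nondimensionalize(ga_phys_no_plas, long_geom)


@pytest.fixture(scope="session")
def linear_fit():
    """The 20 -> 200 um linearly varying 20-cell file."""
    return cf.fit_linear_file(20.0, 200.0, 0.1, 0.9, 20, 0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230913)
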