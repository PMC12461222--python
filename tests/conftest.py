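"""Shared fixtures: small phantoms, geometries and system matrices."""

import numpy as np
import pytest

import cbctlab as cl


@pytest.fixture(scope="session")
def toy_phantom():
    return cl.make_toy_phantom()


@pytest.fixture(scope="session")
def toy_matrix():
    return cl.build_system_matrix(cl.toy_geometry(), (3, 3), 1.0)


@pytest.fixture(scope="session")
def toy_spectrum():
    return cl.SPECTRUM_PRESETS["toy_bichromatic"]


@pytest.fixture(scope="session")
def dental64():
    return cl.make_dental_phantom(64, seed=1)


@pytest.fixture(scope="session")
def dental64_metal(dental64):
    ph = cl.insert_metal(dental64, (42, 26), 3)
    return cl.insert_metal(ph, (42, 40), 3)


@pytest.fixture(scope="session")
def par_geom90():
    return cl.parallel_geometry(90, 95)


@pytest.fixture(scope="session")
def sm64(par_geom90, dental64):
    return cl.build_system_matrix(par_geom90, dental64.shape, 1.0)


@pytest.fixture(scope="session")
def dental_spectrum():
    return cl.SPECTRUM_PRESETS["dental_bichromatic"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
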