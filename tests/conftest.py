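"""Shared fixtures: one mid-sized synthetic study generated once per session."""

import numpy as np
import pytest

from crossmodalfc.mapping import fit_all_regions
from crossmodalfc.synthetic import (
    SyntheticConfig,
    make_band_fc_set,
    make_crossmodal_truth,
    make_geometry,
)

SESSION_SEED = 1


@pytest.fixture(scope="session")
def config200():
    return SyntheticConfig(n_parcels=200, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def geometry200(config200):
    return make_geometry(config200.n_parcels, seed=config200.seed)


@pytest.fixture(scope="session")
def bands200(geometry200, config200):
    return make_band_fc_set(geometry200, config200)


@pytest.fixture(scope="session")
def crossmodal200(bands200, geometry200, config200):
    """(haemodynamic matrix, ground truth) with hierarchy-graded noise."""
    return make_crossmodal_truth(bands200, geometry200, config200)


@pytest.fixture(scope="session")
def r2_map200(crossmodal200, bands200):
    haemo, _ = crossmodal200
    _, r2_map = fit_all_regions(haemo, bands200)
    return r2_map


@pytest.fixture(scope="session")
def small_geometry():
    return make_geometry(40, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
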