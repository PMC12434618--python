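"""Shared session fixtures: meshes, models and solves reused across tests.

Everything here is deterministic (fixed configs, fixed seeds), so reuse
across tests is safe and keeps the suite fast: the expensive objects are
the factorized FEM operators and the 45-point DC sweep.
"""

import warnings

import pytest

from menpsim.analysis import dc_sweep
from menpsim.config import default_scenario
from menpsim.coupled import Model

warnings.filterwarnings(
    "ignore", message="shell electrical conductivity is stored but ignored.*")


@pytest.fixture(scope="session")
def bv_config():
    return default_scenario("BV")


@pytest.fixture(scope="session")
def bv_model(bv_config):
    return Model(bv_config)


@pytest.fixture(scope="session")
def cm_model():
    return Model(default_scenario("CM"))


@pytest.fixture(scope="session")
def sol_2t(bv_model):
    return bv_model.stationary(2.0)


@pytest.fixture(scope="session")
def sweep_records(bv_config, bv_model):
    return dc_sweep(bv_config, model=bv_model)


@pytest.fixture(scope="session")
def fine_model():
    cfg = default_scenario("BV")
    cfg.mesh_resolution = "fine"
    return Model(cfg)
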