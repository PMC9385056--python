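"""Shared fixtures: scenarios at test scale and precomputed whole-body runs.

Population runs use 400 units per regeneration cycle; convergence to the
full-scale (5000-unit) reference is itself covered by a test.
"""
import numpy as np
import pytest

from aspicox.params import Regimen
from aspicox.pk import solve_pk
from aspicox.population import simulate_regimen
from aspicox.scenarios import et_scenario, healthy_scenario


N_UNITS = 400


@pytest.fixture(scope="session")
def healthy():
    return healthy_scenario(n_units=N_UNITS)


@pytest.fixture(scope="session")
def et():
    return et_scenario(n_units=N_UNITS)


@pytest.fixture(scope="session")
def pk_single(healthy):
    """Single 100 mg dose, fine grid."""
    reg = Regimen(dose=100.0, interval=24.0, n_doses=1)
    return solve_pk(healthy.pk, reg, 0.0, 12.0, dt=0.005)


@pytest.fixture(scope="session")
def traj_100od(healthy):
    """Healthy whole-body run: 100 mg od for 3 weeks plus full recovery."""
    return simulate_regimen(Regimen.from_schedule(100.0, "od"), healthy)


@pytest.fixture(scope="session")
def traj_50bid(healthy):
    return simulate_regimen(Regimen.from_schedule(50.0, "bid"), healthy)


@pytest.fixture(scope="session")
def traj_free(healthy):
    """Sham (0 mg) regimen: drug-free reference ensemble."""
    return simulate_regimen(Regimen(dose=0.0, interval=24.0, n_doses=21), healthy)
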