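"""Scenario packaging, dose grids, synthetic observations, F inference."""
import numpy as np
import pytest

from aspicox.params import Regimen
from aspicox.population import simulate_regimen
from aspicox.scenarios import (generate_observations, get_scenario,
                               infer_bioavailability, obese_scenario,
                               run_dose_grid, scenario_diff)

N = 300  # units per cycle for the runs in this module


def test_packaged_scenarios_load(healthy, et):
    assert healthy.label == "healthy" and et.label == "ET"
    assert get_scenario("obese").pk.F == pytest.approx(0.2)
    with pytest.raises(KeyError):
        get_scenario("martian")


def test_et_diff_touches_exactly_the_documented_parameters(healthy, et):
    """ET vs healthy: MK-stage durations, production, platelet count + flux,
    platelet half-life — and nothing else."""
    diff = scenario_diff(healthy, et)
    assert set(diff) == {
        "pd.phi_max",
        "unit.T_mat", "unit.T_burst", "unit.L_MK", "unit.t_half_P",
        "unit.p_ss", "unit.p_burst",
        "population.platelet_count",
    }
    # directions: shorter MK life, more production, more platelets, more flux
    assert diff["unit.L_MK"][1] < diff["unit.L_MK"][0]
    assert diff["unit.p_ss"][1] > diff["unit.p_ss"][0]
    assert diff["population.platelet_count"][1] > diff["population.platelet_count"][0]
    assert diff["pd.phi_max"][1] > diff["pd.phi_max"][0]
    # flux increase proportional to the platelet count
    assert diff["pd.phi_max"][1] / diff["pd.phi_max"][0] == pytest.approx(
        diff["population.platelet_count"][1] / diff["population.platelet_count"][0])


def test_obese_diff_is_bioavailability_only(healthy):
    diff = scenario_diff(
        healthy, obese_scenario(F=0.2, n_units=healthy.population.n_units))
    assert set(diff) == {"pk.F"}


def test_lower_bioavailability_never_deepens_inhibition(healthy):
    sc = healthy.model_copy(update={
        "population": healthy.population.model_copy(update={"n_units": N})})
    reg = Regimen.from_schedule(100.0, "od", days=5)
    full = simulate_regimen(reg, sc)
    halved = simulate_regimen(
        reg, sc.model_copy(update={"pk": sc.pk.model_copy(update={"F": 0.5})}))
    assert np.all(halved.X_percent >= full.X_percent - 1e-9)


def test_dose_grid_table_complete_and_reproducible(healthy):
    sc = healthy.model_copy(update={
        "population": healthy.population.model_copy(update={"n_units": N})})
    a = run_dose_grid(sc, [50.0, 100.0], ["od"], weeks=1.0)
    b = run_dose_grid(sc, [50.0, 100.0], ["od"], weeks=1.0)
    assert len(a.table) == 2
    assert (a.table.fillna(0.0) == b.table.fillna(0.0)).all().all()
    row = a.row(100.0, "od")
    assert row.stxb2_nadir_ss <= row.stxb2_mean_ss <= row.stxb2_peak_ss


@pytest.fixture(scope="module")
def obs_setup(healthy):
    sc = healthy.model_copy(update={
        "population": healthy.population.model_copy(update={"n_units": N})})
    reg = Regimen.from_schedule(325.0, "od", days=7)
    times = 24.0 * np.arange(1.0, 8.0) - 0.5
    return sc, reg, times


class TestSyntheticObservations:
    def test_zero_noise_returns_exact_profile(self, obs_setup):
        sc, reg, times = obs_setup
        a = generate_observations(sc, reg, times, 0.0, seed=1)
        b = generate_observations(sc, reg, times, 0.0, seed=2)
        assert np.array_equal(a.values, b.values)   # no noise, seed irrelevant

    def test_seed_reproducibility_and_independence(self, obs_setup):
        sc, reg, times = obs_setup
        a = generate_observations(sc, reg, times, 0.10, seed=11)
        b = generate_observations(sc, reg, times, 0.10, seed=11)
        c = generate_observations(sc, reg, times, 0.10, seed=12)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        clean = generate_observations(sc, reg, times, 0.0, seed=0)
        # different seeds share the same underlying mean profile
        for noisy in (a, c):
            assert np.all(noisy.values >= 0.0)
            rel = noisy.values[clean.values > 1.0] / clean.values[clean.values > 1.0]
            assert np.all(np.abs(rel - 1.0) < 0.5)

    def test_negative_noise_rejected(self, obs_setup):
        sc, reg, times = obs_setup
        with pytest.raises(ValueError):
            generate_observations(sc, reg, times, -0.1, seed=1)

    def test_times_outside_window_rejected(self, obs_setup):
        sc, reg, _ = obs_setup
        with pytest.raises(ValueError):
            generate_observations(sc, reg, np.array([1e6]), 0.0, seed=1)


def test_noise_free_bioavailability_recovered_exactly(healthy):
    """Self-consistency: data generated at F=1 fit back to F=1, zero residual."""
    sc = obese_scenario(F=1.0, n_units=N)
    reg = Regimen.from_schedule(325.0, "od", days=7)
    times = 24.0 * np.arange(1.0, 8.0) - 0.5
    obs = generate_observations(sc, reg, times, 0.0, seed=3)
    fit = infer_bioavailability(obs, sc, reg, F_grid=[0.2, 0.6, 1.0])
    assert fit.F_best == 1.0
    assert fit.sse[1.0] == pytest.approx(0.0, abs=1e-12)
    assert fit.sse[0.2] > 1.0
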