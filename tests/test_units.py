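"""Single-unit COX-1 dynamics: flux law, stage profiles, solver cross-check."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aspicox.params import PDParameters, Regimen, UnitParameters
from aspicox.pk import solve_pk
from aspicox.units import (acetylation_flux, destruction_rate, hill_rate,
                           platelet_count_profile, production_rate,
                           regimen_over_unit_life, solve_single_unit,
                           solve_units_fast, transfer_rate, unit_rhs)

PD = PDParameters(phi_max=0.2, K_a50=1.5, h=3.0, w_portal=0.15)


class TestAcetylationFlux:
    def test_no_drug_no_flux(self):
        assert acetylation_flux(5.0, 0.0, PD) == 0.0

    def test_half_saturation_point_is_exact(self):
        # analytic property of the Hill form, any h
        for h in (1.0, 2.0, 6.5):
            pd = PD.model_copy(update={"h": h})
            assert acetylation_flux(4.0, pd.K_a50, pd) == pytest.approx(
                0.5 * pd.phi_max * 4.0, rel=1e-12)

    def test_saturates_at_phi_max_times_x(self):
        assert acetylation_flux(4.0, 1e9, PD) == pytest.approx(0.2 * 4.0, rel=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            acetylation_flux(-1.0, 1.0, PD)
        with pytest.raises(ValueError):
            hill_rate(-0.5, PD)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(0, 1e3), a1=st.floats(0, 1e3), a2=st.floats(0, 1e3))
    def test_monotone_in_both_arguments(self, x, a1, a2):
        lo, hi = sorted((a1, a2))
        assert acetylation_flux(x, lo, PD) <= acetylation_flux(x, hi, PD) + 1e-12
        assert acetylation_flux(x, a1, PD) <= acetylation_flux(x + 1.0, a1, PD) + 1e-12


class TestStageProfiles:
    def test_production_zero_outside_mk_life(self, healthy):
        u = healthy.unit
        s = np.array([-1.0, u.L_MK, u.L_MK + 50.0])
        assert np.all(production_rate(s, u) == 0.0)
        assert production_rate(u.T_burst / 2, u) == u.p_burst
        assert production_rate((u.T_burst + u.T_mat) / 2, u) == u.p_ss

    def test_transfer_confined_to_proliferation(self, healthy):
        u = healthy.unit
        assert transfer_rate(u.T_mat - 1.0, u) == 0.0
        assert transfer_rate(u.L_MK + 1.0, u) == 0.0
        assert transfer_rate(u.L_MK - 1e-6, u) == pytest.approx(u.k5_ss, rel=1e-4)

    def test_count_profile_plateau_and_extinction(self, healthy):
        u = healthy.unit
        assert platelet_count_profile(u.L_MK + 1.0, u) == 1.0
        assert platelet_count_profile(u.span, u) == 0.0
        assert platelet_count_profile(u.T_mat - 1.0, u) == 0.0

    def test_destruction_hazard_only_during_apoptotic_decline(self, healthy):
        u = healthy.unit
        assert destruction_rate(u.T_mat + u.L_P - 1.0, u) == 0.0
        assert destruction_rate(u.T_mat + u.L_P + 1.0, u) > 0.0


class TestUnitDynamics:
    def test_dead_unit_has_zero_derivatives(self, healthy):
        y = np.array([1.0, 1.0, 2.0, 2.0])
        d = unit_rhs(y, healthy.unit.span + healthy.unit.tau + 1.0,
                     healthy.unit, healthy.pd, 1.0, 1.0)
        assert np.all(d == 0.0)

    def test_drug_free_unit_stays_fully_unacetylated(self, healthy):
        u = healthy.unit
        sham = Regimen(dose=0.0, interval=24.0, n_doses=1)
        pk = solve_pk(healthy.pk, sham, 0.0, u.span + 1.0, dt=0.05)
        traj = solve_units_fast(np.array([0.0]), u, healthy.pd, pk, 0.2)
        f = traj.platelet_fraction(0)
        assert np.nanmax(np.abs(f - 100.0)) < 1e-9
        fm = traj.mk_fraction(0)
        assert np.nanmax(np.abs(fm - 100.0)) < 1e-9

    def test_totals_equal_unacetylated_when_flux_is_off(self, healthy):
        u = healthy.unit
        pd0 = healthy.pd.model_copy(update={"phi_max": 0.0})
        reg = regimen_over_unit_life(u, 100.0, 24.0)
        pk = solve_pk(healthy.pk, reg, 0.0, u.span + 1.0, dt=0.05)
        traj = solve_units_fast(np.array([0.0]), u, pd0, pk, 0.2)
        assert np.allclose(traj.x_MK[0], traj.x_MK_tot)
        assert np.allclose(traj.x_P[0], traj.x_P_tot)

    def test_ode_route_matches_exponential_integrator(self, healthy):
        """The two independent solvers agree on a dosed unit trajectory."""
        u = healthy.unit
        reg = regimen_over_unit_life(u, 100.0, 24.0)
        pk = solve_pk(healthy.pk, reg, 0.0, u.span + 1.0, dt=0.01)
        grid = np.arange(0.0, u.span, 0.5)
        ode = solve_single_unit(u, pk, healthy.pd, grid)
        fast = solve_units_fast(np.array([0.0]), u, healthy.pd, pk, 0.25)
        # compare on the shared grid nodes, away from stage boundaries
        on_grid = np.isin(np.round(fast.s * 4), np.round(grid * 4))
        common = (fast.s > 1.0) & (fast.s < u.span - 1.0) & on_grid
        s_common = fast.s[common]
        for get in ("platelet_fraction", "mk_fraction"):
            a = np.interp(s_common, grid, getattr(ode, get)(0))
            b = getattr(fast, get)(0)[common]
            mask = ~np.isnan(a) & ~np.isnan(b)
            assert np.max(np.abs(a[mask] - b[mask])) < 0.05   # pp

    def test_dose_monotonicity_of_unacetylated_fraction(self, healthy):
        u = healthy.unit
        prev = None
        for dose in (0.0, 50.0, 100.0, 200.0):
            reg = regimen_over_unit_life(u, dose, 24.0)
            pk = solve_pk(healthy.pk, reg, 0.0, u.span + 1.0, dt=0.02)
            f = solve_units_fast(np.array([0.0]), u, healthy.pd, pk, 0.2
                                 ).platelet_fraction(0)
            if prev is not None:
                mask = ~np.isnan(f) & ~np.isnan(prev)
                assert np.all(f[mask] <= prev[mask] + 1e-9)
            prev = f

    def test_endpoints_stable_under_grid_refinement(self, healthy):
        u = healthy.unit
        reg = regimen_over_unit_life(u, 100.0, 24.0)
        pk = solve_pk(healthy.pk, reg, 0.0, u.span + 1.0, dt=0.01)
        e1 = solve_units_fast(np.array([0.0]), u, healthy.pd, pk, 0.2).endpoints(u)
        e2 = solve_units_fast(np.array([0.0]), u, healthy.pd, pk, 0.1).endpoints(u)
        for k in e1:
            assert abs(e1[k] - e2[k]) < 0.1

    def test_grid_outside_pk_coverage_rejected(self, healthy):
        u = healthy.unit
        reg = Regimen(dose=100.0, interval=24.0, n_doses=1)
        pk = solve_pk(healthy.pk, reg, 0.0, 10.0)
        with pytest.raises(ValueError):
            solve_single_unit(u, pk, healthy.pd, np.arange(0.0, 100.0, 1.0))
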