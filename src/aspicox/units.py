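"""COX-1 turnover in a single megakaryocyte(MK)-platelet unit.

Two solution routes are provided and cross-checked in the test suite:

* :func:`solve_single_unit` — a conventional stiff ODE integration of
  :func:`unit_rhs` against a precomputed PK trajectory (LSODA, restarted at
  every dose event and stage boundary);
* :func:`solve_units_fast` — an exact exponential-integrator solve that
  exploits the fact that, given the aspirin concentration time course, each
  unit's equations are *linear* in the COX-1 amounts: the acetylation flux is
  bilinear (linear in COX-1, Hill only in aspirin).  It is vectorised over
  many units and is the engine behind the population simulator.

All unit dynamics live on the age axis ``s = t - tau``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .params import PDParameters, Regimen, UnitParameters, UnitState
from .pk import PKSolution

__all__ = [
    "acetylation_flux",
    "hill_rate",
    "platelet_hill_rate",
    "production_rate",
    "transfer_rate",
    "degradation_rate",
    "destruction_rate",
    "platelet_count_profile",
    "unit_rhs",
    "solve_single_unit",
    "solve_units_fast",
    "UnitTrajectory",
]

# destruction hazard cap during the apoptotic decline; the true hazard of a
# linear count decline diverges at pool extinction.  The cap only affects the
# last ~0.2 h of a unit's platelet pool (< 1e-3 of its COX-1 mass) and cancels
# exactly in every unacetylated/total ratio.
K6_MAX = 5.0


def hill_rate(a_conc, pd: PDParameters):
    """Fractional acetylation rate [1/h]: ``phi_max * a^h / (K^h + a^h)``."""
    a = np.asarray(a_conc, dtype=float)
    if np.any(a < 0):
        raise ValueError("aspirin concentration must be nonnegative")
    # evaluated as phi / (1 + (K/a)^h): immune to overflow of a^h or K^h
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(a > 0, pd.K_a50 / np.where(a > 0, a, 1.0), np.inf)
        out = pd.phi_max / (1.0 + ratio ** pd.h)
    out = np.where(a > 0, out, 0.0)
    return out if out.ndim else float(out)


def acetylation_flux(x, a_conc, pd: PDParameters):
    """COX-1 acetylation flux [au/h], bilinear in COX-1, Hill in aspirin.

    Because the flux is proportional to the COX-1 amount ``x``, the
    whole-body maximal flux scales with the circulating platelet count (more
    platelets carry more COX-1) without any additional coupling.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("COX-1 amount must be nonnegative")
    out = x * hill_rate(a_conc, pd)
    return out if out.ndim else float(out)


def platelet_hill_rate(a_blood_conc, a_portal_conc, pd: PDParameters):
    """Fractional acetylation rate of circulating platelets [1/h].

    Platelets transit both systemic and portal blood; their exposure is the
    ``w_portal``-weighted mixture of the two concentration sigmoids.  The
    briefly high pre-extraction portal concentrations keep low doses
    pharmacologically active even when the systemic peak stays below K_a50.
    """
    return ((1.0 - pd.w_portal) * hill_rate(a_blood_conc, pd)
            + pd.w_portal * hill_rate(a_portal_conc, pd))


# -- stage profiles on the age axis -----------------------------------------

def production_rate(s, u: UnitParameters):
    """COX-1 production p(s) [au/h]: burst, then steady state, zero after MK death."""
    s = np.asarray(s, dtype=float)
    out = np.where(s < u.T_burst, u.p_burst, u.p_ss)
    out = np.where((s < 0) | (s >= u.L_MK), 0.0, out)
    return out if out.ndim else float(out)


def degradation_rate(s, u: UnitParameters):
    """COX-1 degradation in MKs, kd_x(s) [1/h]."""
    s = np.asarray(s, dtype=float)
    out = np.where((s >= 0) & (s < u.L_MK), u.kd_x_ss, 0.0)
    return out if out.ndim else float(out)


def transfer_rate(s, u: UnitParameters):
    """MK -> platelet transfer k5(s) [1/h], active during proliferation.

    ``k5(s) = k5_ss * u**k5_shape`` with ``u`` the normalised position inside
    the proliferation stage: platelet output rises with MK maturity (ploidy)
    when ``k5_shape > 0`` and is constant when it is 0.
    """
    s = np.asarray(s, dtype=float)
    active = (s >= u.T_mat) & (s < u.L_MK)
    if u.L_MK > u.T_mat:
        frac = np.clip((s - u.T_mat) / (u.L_MK - u.T_mat), 0.0, 1.0)
    else:
        frac = np.ones_like(s)
    out = np.where(active, u.k5_ss * frac ** u.k5_shape, 0.0)
    return out if out.ndim else float(out)


def platelet_count_profile(s, u: UnitParameters):
    """Relative platelet number of the unit (peak = 1).

    Rises with cumulative platelet release (matching the transfer-rate ramp),
    stays constant during the platelet lifespan, declines linearly to zero
    during the apoptotic phase.
    """
    s = np.asarray(s, dtype=float)
    if u.L_MK > u.T_mat:
        rise = np.clip((s - u.T_mat) / (u.L_MK - u.T_mat), 0.0, 1.0) ** (u.k5_shape + 1.0)
    else:
        rise = 1.0
    s_decl = u.T_mat + u.L_P
    s_end = u.span
    fall = (s_end - s) / (s_end - s_decl)
    out = np.minimum(np.clip(rise, 0.0, 1.0), np.clip(fall, 0.0, 1.0))
    out = np.where((s < u.T_mat) | (s >= s_end), 0.0, out)
    return out if out.ndim else float(out)


def destruction_rate(s, u: UnitParameters):
    """Peripheral platelet destruction hazard k6(s) [1/h].

    Zero during release and plateau; during the apoptotic decline it is the
    hazard of the linear count profile, ``1 / (s_end - s)``, capped at
    :data:`K6_MAX`.
    """
    s = np.asarray(s, dtype=float)
    s_decl = u.T_mat + u.L_P
    s_end = u.span
    with np.errstate(divide="ignore"):
        haz = 1.0 / np.maximum(s_end - s, 1.0 / K6_MAX)
    out = np.where((s >= s_decl) & (s < s_end), haz, 0.0)
    return out if out.ndim else float(out)


# -- ODE route ----------------------------------------------------------------

def unit_rhs(state, t: float, unit: UnitParameters, pd: PDParameters,
             a_tissue_conc: float, a_blood_conc: float,
             a_portal_conc: float = 0.0) -> np.ndarray:
    """Right-hand side for ``(x_MK, x_P, x_MK_tot, x_P_tot)`` at time ``t``.

    MKs (bone marrow, tissue compartment) are exposed to the tissue aspirin
    concentration; circulating platelets to the portal/systemic blood
    mixture.  The totals obey the same turnover equations without the
    acetylation terms.  Outside the unit's life support ``[tau, tau + span]``
    all derivatives are zero (dead unit).
    """
    if isinstance(state, UnitState):
        state = np.array([state.x_MK, state.x_P, state.x_MK_tot, state.x_P_tot])
    x_mk, x_p, x_mk_tot, x_p_tot = state
    s = t - unit.tau
    if s < 0 or s >= unit.span:
        return np.zeros(4)
    p = production_rate(s, unit)
    kd = degradation_rate(s, unit)
    k5 = transfer_rate(s, unit)
    k6 = destruction_rate(s, unit)
    phi_T = hill_rate(a_tissue_conc, pd)
    phi_B = platelet_hill_rate(a_blood_conc, a_portal_conc, pd)
    return np.array([
        p - (kd + k5 + phi_T) * x_mk,
        k5 * x_mk - (k6 + phi_B) * x_p,
        p - (kd + k5) * x_mk_tot,
        k5 * x_mk_tot - k6 * x_p_tot,
    ])


@dataclass
class UnitTrajectory:
    """COX-1 amounts of one or more units on a shared age grid."""

    s: np.ndarray                    # unit age [h]
    tau: np.ndarray                  # (n_units,)
    x_MK: np.ndarray                 # (n_units, n_s) unacetylated [au]
    x_P: np.ndarray
    x_MK_tot: np.ndarray             # totals are drug-free, shared shape (n_s,)
    x_P_tot: np.ndarray

    def mk_fraction(self, i: int = 0) -> np.ndarray:
        """Unacetylated MK COX-1 as % of total, NaN where the MK pool is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.x_MK[i] / np.where(self.x_MK_tot > 0, self.x_MK_tot, np.nan)

    def platelet_fraction(self, i: int = 0) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.x_P[i] / np.where(self.x_P_tot > 0, self.x_P_tot, np.nan)

    def endpoints(self, unit: UnitParameters, i: int = 0) -> dict[str, float]:
        """Fig-style endpoint summary of unit ``i`` [% of total COX-1]:

        MK fraction at the end of MK life, platelet fraction at the start of
        the platelet-only phase (end of release) and at the end of the unit.
        """
        f_mk = self.mk_fraction(i)
        f_p = self.platelet_fraction(i)
        i_mk = int(np.searchsorted(self.s, unit.L_MK) - 1)
        i_p0 = int(np.searchsorted(self.s, unit.L_MK))
        valid = np.where(~np.isnan(f_p))[0]
        return {
            "mk_end": float(f_mk[i_mk]),
            "platelet_start": float(f_p[min(i_p0, valid[-1])]),
            "platelet_end": float(f_p[valid[-1]]),
        }


def solve_single_unit(unit: UnitParameters, pk_traj: PKSolution, pd: PDParameters,
                      grid: np.ndarray,
                      rtol: float = 1e-8, atol: float = 1e-10) -> UnitTrajectory:
    """Integrate one unit's ODEs against a precomputed PK trajectory.

    ``grid`` is an absolute-time grid; it must be covered by ``pk_traj``
    (times outside the PK solution would silently read zero drug).  The
    integration restarts at every dose event and stage boundary so LSODA
    never steps across a discontinuity of the right-hand side.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < pk_traj.t[0] - 1e-9 or grid[-1] > pk_traj.t[-1] + 1e-9:
        raise ValueError("time grid is not covered by the PK trajectory")

    def rhs(t, y):
        cT = pk_traj.conc_tissue_at(t)
        cB = pk_traj.conc_blood_at(t)
        cS = pk_traj.conc_portal_at(t)
        return unit_rhs(y, t, unit, pd, cT, cB, cS)

    breaks = {unit.tau + b for b in
              (0.0, unit.T_burst, unit.T_mat, unit.L_MK, unit.T_mat + unit.L_P, unit.span)}
    if pk_traj.regimen is not None:
        breaks.update(pk_traj.regimen.times.tolist())
    breaks = sorted(b for b in breaks if grid[0] < b < grid[-1])
    edges = [grid[0]] + breaks + [grid[-1]]

    y = np.zeros(4)
    out = np.zeros((4, grid.size))
    out[:, 0] = y
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1e-12:
            continue
        mask = (grid > a) & (grid <= b)
        t_eval = grid[mask]
        # always evaluate at the segment end so the next segment restarts there
        t_req = t_eval if t_eval.size and abs(t_eval[-1] - b) < 1e-12 \
            else np.append(t_eval, b)
        # max_step must resolve the ~1 h aspirin concentration pulses that the
        # interpolated PK forcing injects between dose events
        sol = integrate.solve_ivp(rhs, (a, b), y, t_eval=t_req,
                                  method="LSODA", rtol=rtol, atol=atol,
                                  max_step=min(max((b - a) / 4, 1e-3), 0.2))
        if t_eval.size:
            out[:, mask] = sol.y[:, :t_eval.size]
        y = sol.y[:, -1].copy()
        np.clip(y, 0.0, None, out=y)
    np.clip(out, 0.0, None, out=out)
    return UnitTrajectory(
        s=grid - unit.tau, tau=np.array([unit.tau]),
        x_MK=out[0][None, :], x_P=out[1][None, :],
        x_MK_tot=out[2], x_P_tot=out[3],
    )


# -- exact exponential-integrator engine -------------------------------------

def _exposure_integrals(pk: PKSolution, pd: PDParameters):
    """Cumulative acetylation exposure Phi(t) = int phi_rate dt on the PK grid."""
    rate_T = hill_rate(pk.conc_tissue, pd)
    rate_B = platelet_hill_rate(pk.conc_blood, pk.conc_portal, pd)
    Phi_T = integrate.cumulative_trapezoid(rate_T, pk.t, initial=0.0)
    Phi_B = integrate.cumulative_trapezoid(rate_B, pk.t, initial=0.0)
    return Phi_T, Phi_B


def solve_units_fast(taus: np.ndarray, unit: UnitParameters, pd: PDParameters,
                     pk: PKSolution, ds: float) -> UnitTrajectory:
    """Exactly solve many birth-shifted units at once.

    Given the PK trajectory, each unit's COX-1 amounts obey scalar linear
    ODEs; over one age step the homogeneous part decays by
    ``exp(-(turnover + acetylation-exposure increment))`` and the production /
    transfer source is applied at the step midpoint with half-step decay
    (second-order accurate; the decay itself is exact).

    The drug-free totals are identical for every unit and are computed once.
    """
    taus = np.asarray(taus, dtype=float)
    n_s = int(round(unit.span / ds))
    s = ds * np.arange(n_s + 1)
    s_mid = s[:-1] + ds / 2

    kd = degradation_rate(s_mid, unit)
    k5 = transfer_rate(s_mid, unit)
    k6 = destruction_rate(s_mid, unit)
    # exact per-step integral of the capped apoptotic hazard
    k6_int = _k6_step_integrals(s, unit)
    p_src = production_rate(s_mid, unit) * ds
    dA0 = (kd + k5) * ds
    dB0 = k6_int

    # cumulative acetylation exposure, interpolated at every (tau + s) node
    Phi_T, Phi_B = _exposure_integrals(pk, pd)
    t_nodes = taus[:, None] + s[None, :]
    PT = np.interp(t_nodes, pk.t, Phi_T)
    PB = np.interp(t_nodes, pk.t, Phi_B)
    dPT = np.diff(PT, axis=1)
    dPB = np.diff(PB, axis=1)

    n_u = taus.size
    x_mk = np.zeros((n_u, n_s + 1))
    x_p = np.zeros((n_u, n_s + 1))
    tot_mk = np.zeros(n_s + 1)
    tot_p = np.zeros(n_s + 1)

    for j in range(n_s):
        # totals: drug-free recurrence (shared by all units)
        ea0 = np.exp(-dA0[j])
        eb0 = np.exp(-dB0[j])
        mk_old0 = tot_mk[j]
        tot_mk[j + 1] = mk_old0 * ea0 + p_src[j] * np.sqrt(ea0)
        inflow0 = k5[j] * ds * 0.5 * (mk_old0 + tot_mk[j + 1])
        tot_p[j + 1] = tot_p[j] * eb0 + inflow0 * np.sqrt(eb0)
        # drugged units
        ea = np.exp(-(dA0[j] + dPT[:, j]))
        eb = np.exp(-(dB0[j] + dPB[:, j]))
        mk_old = x_mk[:, j]
        x_mk[:, j + 1] = mk_old * ea + p_src[j] * np.sqrt(ea)
        inflow = k5[j] * ds * 0.5 * (mk_old + x_mk[:, j + 1])
        x_p[:, j + 1] = x_p[:, j] * eb + inflow * np.sqrt(eb)

    # MKs die at L_MK: clear any residual numerical dust past the boundary
    dead = s >= unit.L_MK
    x_mk[:, dead] = 0.0
    tot_mk[dead] = 0.0
    return UnitTrajectory(s=s, tau=taus, x_MK=x_mk, x_P=x_p,
                          x_MK_tot=tot_mk, x_P_tot=tot_p)


def _k6_step_integrals(s: np.ndarray, u: UnitParameters) -> np.ndarray:
    """Exact integral of the (capped) destruction hazard over each age step."""
    s_decl = u.T_mat + u.L_P
    s_end = u.span
    s_cap = s_end - 1.0 / K6_MAX
    lo = np.clip(s[:-1], s_decl, s_cap)
    hi = np.clip(s[1:], s_decl, s_cap)
    out = np.log((s_end - lo) / (s_end - hi))
    lo2 = np.clip(s[:-1], s_cap, s_end)
    hi2 = np.clip(s[1:], s_cap, s_end)
    return out + K6_MAX * (hi2 - lo2)


def regimen_over_unit_life(unit: UnitParameters, dose: float, interval: float,
                           first_dose: float = 0.0) -> Regimen:
    """Dosing at the given interval covering the unit's entire lifespan."""
    n = max(1, int(np.ceil((unit.span - first_dose) / interval)))
    return Regimen(dose=dose, interval=interval, n_doses=n, start=first_dose)
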