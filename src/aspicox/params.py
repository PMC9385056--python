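"""Parameter and state containers for the aspirin / COX-1 turnover model.

All containers are immutable pydantic models so that a loaded configuration
cannot drift silently during a simulation.  Conventions used throughout the
package:

* time is measured in **hours**,
* drug amounts in **mg**, concentrations in **mg/L** (via the distribution
  volumes ``V_B``, ``V_T``),
* COX-1 amounts are in arbitrary units; whole-body trajectories are reported
  both as percent of total (acetylated + unacetylated) COX-1 and as an
  absolute amount in those arbitrary units.
"""
from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PKParameters",
    "PKState",
    "PDParameters",
    "UnitParameters",
    "UnitState",
    "Regimen",
    "PopulationConfig",
    "Scenario",
    "SENSITIVITY_PARAMETERS",
    "perturbed_scenario",
]


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class PKParameters(_Frozen):
    """Rate constants and volumes of the linear three-compartment aspirin PK.

    Oral input enters a gastrointestinal depot and is absorbed (rate ``ka``,
    scaled by the systemic bioavailability fraction ``F``) into portal blood.
    Portal blood feeds systemic blood, attenuated by the hepatic extraction
    fraction ``k_he``; systemic blood exchanges with the tissue compartment
    that houses the bone-marrow megakaryocytes.  Each compartment loses drug
    to hydrolysis at its own ``kd_*`` rate.
    """

    ka: float = Field(gt=0, description="GI absorption rate constant [1/h]")
    k1: float = Field(ge=0, description="systemic blood -> tissue exchange [1/h]")
    k2: float = Field(ge=0, description="tissue -> systemic blood exchange [1/h]")
    k3: float = Field(ge=0, description="portal -> systemic transfer [1/h]")
    k4: float = Field(ge=0, description="systemic -> portal backflow [1/h]")
    kd_T: float = Field(ge=0, description="hydrolysis in tissue [1/h]")
    kd_B: float = Field(ge=0, description="hydrolysis in systemic blood [1/h]")
    kd_S: float = Field(ge=0, description="hydrolysis in portal blood [1/h]")
    k_he: float = Field(ge=0, le=1, description="hepatic extraction fraction [-]")
    F: float = Field(gt=0, le=1, default=1.0, description="systemic bioavailability [-]")
    V_B: float = Field(gt=0, description="systemic blood distribution volume [L]")
    V_T: float = Field(gt=0, description="tissue distribution volume [L]")
    V_S: float = Field(gt=0, default=1.0, description="portal blood distribution volume [L]")


class PKState(_Frozen):
    """Aspirin amounts [mg] in the three drug compartments at time ``t`` [h]."""

    A_T: float = Field(ge=0)
    A_S: float = Field(ge=0)
    A_B: float = Field(ge=0)
    t: float = 0.0


class PDParameters(_Frozen):
    """Hill parameters of the irreversible COX-1 acetylation flux.

    The flux is bilinear in the COX-1 amount and sigmoidal in the aspirin
    concentration: ``phi = phi_max * x * a**h / (K_a50**h + a**h)``.  Because
    the flux is proportional to the COX-1 amount, the whole-body maximal
    acetylation flux scales with the circulating platelet count without any
    extra coupling.

    Circulating platelets pass through both portal and systemic blood;
    ``w_portal`` is the portal share of their acetylation exposure (MKs, in
    the tissue compartment, see tissue concentration only).
    """

    phi_max: float = Field(ge=0, description="maximal fractional acetylation rate [1/h]")
    K_a50: float = Field(gt=0, description="half-maximal aspirin concentration [mg/L]")
    h: float = Field(ge=1, description="Hill coefficient [-]")
    w_portal: float = Field(ge=0, le=1, default=0.15,
                            description="portal-blood share of platelet exposure [-]")


class UnitParameters(_Frozen):
    """One megakaryocyte(MK)-platelet unit: a cohort of MKs born at ``tau``.

    The unit's life unfolds on the age axis ``s = t - tau``:

    * ``[0, T_mat)``      MK maturation; COX-1 production with an initial
      transcription burst (rate ``p_burst`` for ``s < T_burst``, then
      ``p_ss``); degradation at ``kd_x_ss``.
    * ``[T_mat, L_MK)``   proliferation: platelets are released (transfer
      rate ``k5_ss``), production continues at ``p_ss``.
    * ``[L_MK, ...)``     MKs are dead; the released platelet pool persists,
      constant in number until ``T_mat + L_P`` and then declining linearly to
      zero at ``L_MK + L_P + T_apop`` (apoptotic phase).

    The platelet lifespan is derived from the measurable platelet half-life:
    ``L_P = 2 * t_half_P`` (deterministic-lifespan reading of a survival
    half-time).  Platelets cannot synthesise COX-1, so their pool only loses
    unacetylated enzyme (acetylation, destruction).
    """

    tau: float = 0.0
    T_mat: float = Field(gt=0, description="MK maturation duration [h]")
    T_burst: float = Field(gt=0, description="duration of the transcription burst [h]")
    L_MK: float = Field(gt=0, description="MK lifetime [h]")
    t_half_P: float = Field(gt=0, description="platelet half-life [h]")
    T_apop: float = Field(gt=0, description="apoptotic decline duration [h]")
    N_P: float = Field(gt=0, default=3000, description="platelets generated per MK [-]")
    p_ss: float = Field(ge=0, description="steady-state COX-1 production rate [au/h]")
    p_burst: float = Field(ge=0, description="burst COX-1 production rate [au/h]")
    kd_x_ss: float = Field(ge=0, description="COX-1 degradation in MKs [1/h]")
    k5_ss: float = Field(ge=0, description="MK->platelet COX-1 transfer rate scale [1/h]")
    k5_shape: float = Field(ge=0, default=0.0,
                            description="exponent of the transfer ramp over proliferation; "
                                        "0 = constant rate, >0 = output rising with MK maturity")

    @model_validator(mode="after")
    def _check_stages(self) -> "UnitParameters":
        if not self.T_mat <= self.L_MK:
            raise ValueError("T_mat must not exceed L_MK (0 < T_mat <= L_MK)")
        if not self.T_burst <= self.T_mat:
            raise ValueError("T_burst must lie within the maturation stage (T_burst <= T_mat)")
        return self

    @property
    def L_P(self) -> float:
        """Platelet lifespan [h], twice the platelet half-life."""
        return 2.0 * self.t_half_P

    @property
    def span(self) -> float:
        """Total unit lifespan [h]: MK life + platelet life + apoptosis."""
        return self.L_MK + self.L_P + self.T_apop


class UnitState(_Frozen):
    """Unacetylated (``x_*``) and total (``x_*_tot``) COX-1 in one unit [au]."""

    x_MK: float = Field(ge=0)
    x_P: float = Field(ge=0)
    x_MK_tot: float = Field(ge=0)
    x_P_tot: float = Field(ge=0)

    @model_validator(mode="after")
    def _check_bounds(self) -> "UnitState":
        if self.x_MK > self.x_MK_tot * (1 + 1e-9) or self.x_P > self.x_P_tot * (1 + 1e-9):
            raise ValueError("unacetylated COX-1 cannot exceed total COX-1")
        return self


class Regimen(_Frozen):
    """A repeated oral dosing schedule.

    ``dose`` in mg (0 is allowed and means sham dosing), doses are given at
    ``start + i * interval`` for ``i = 0..n_doses-1``.
    """

    dose: float = Field(ge=0, description="single administration [mg]")
    interval: float = Field(gt=0, description="dosing interval [h]")
    n_doses: int = Field(ge=1)
    start: float = 0.0

    @classmethod
    def from_schedule(cls, dose: float, schedule: Literal["od", "bid", "tid"],
                      days: float = 21.0, start: float = 0.0) -> "Regimen":
        """Build an od/bid/tid regimen lasting ``days`` days."""
        interval = {"od": 24.0, "bid": 12.0, "tid": 8.0}[schedule]
        n = int(round(days * 24.0 / interval))
        return cls(dose=dose, interval=interval, n_doses=n, start=start)

    @property
    def times(self) -> np.ndarray:
        return self.start + self.interval * np.arange(self.n_doses)

    @property
    def last_dose(self) -> float:
        return self.start + self.interval * (self.n_doses - 1)

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.interval

    @property
    def label(self) -> str:
        name = {24.0: "od", 12.0: "bid", 8.0: "tid"}.get(self.interval, f"q{self.interval:g}h")
        return f"{self.dose:g} mg {name}"


class PopulationConfig(_Frozen):
    """Ensemble settings for the whole-body simulation.

    ``n_units`` is the number of MK-platelet units per regeneration cycle
    (one full unit lifespan); birth times are staggered deterministically so
    that the drug-free ensemble is exactly stationary.
    """

    n_units: int = Field(ge=1, default=5000)
    platelet_count: float = Field(gt=0, default=250e3, description="platelets per uL")
    dt_target: float = Field(gt=0, default=0.25, description="aggregate grid step [h]")
    pre_window: float = Field(ge=0, default=120.0, description="drug-free window before first dose [h]")
    recovery_margin: float = Field(ge=0, default=72.0, description="extra horizon after full turnover [h]")
    pk_dt: float = Field(gt=0, default=0.01, description="fine PK/exposure grid step [h]")


class Scenario(_Frozen):
    """A complete, labelled parameterisation of the model."""

    label: str
    pk: PKParameters
    pd: PDParameters
    unit: UnitParameters
    population: PopulationConfig
    notes: dict[str, str] = Field(default_factory=dict)


# ---------------------------------------------------------------------------
# The 13 parameters subjected to local sensitivity analysis: aspirin PK
# (absorption, portal transit, hepatic extraction, hydrolysis in blood and
# tissue), aspirin PD (the three Hill parameters), and MK/platelet turnover
# (MK lifetime, COX-1 production and degradation in MKs, platelet half-life
# and count).
SENSITIVITY_PARAMETERS: dict[str, tuple[str, str]] = {
    "ka": ("pk", "ka"),
    "k3": ("pk", "k3"),
    "k_he": ("pk", "k_he"),
    "kd_B": ("pk", "kd_B"),
    "kd_T": ("pk", "kd_T"),
    "phi_max": ("pd", "phi_max"),
    "K_a50": ("pd", "K_a50"),
    "h": ("pd", "h"),
    "L_MK": ("unit", "L_MK"),
    "p_ss": ("unit", "p_ss"),
    "kd_x_ss": ("unit", "kd_x_ss"),
    "t_half_P": ("unit", "t_half_P"),
    "platelet_count": ("population", "platelet_count"),
}

PK_PARAMETER_NAMES = [n for n, (sec, _) in SENSITIVITY_PARAMETERS.items() if sec == "pk"]
TURNOVER_PARAMETER_NAMES = ["L_MK", "p_ss", "kd_x_ss", "t_half_P", "platelet_count"]


def perturbed_scenario(scenario: Scenario, name: str, rel_step: float) -> Scenario:
    """Return a copy of ``scenario`` with parameter ``name`` scaled by ``1 + rel_step``.

    ``name`` must be one of :data:`SENSITIVITY_PARAMETERS` or the literal
    ``"dummy"``, which leaves the scenario untouched (useful as a null check
    of the sensitivity machinery).
    """
    if name == "dummy":
        return scenario
    section, field = SENSITIVITY_PARAMETERS[name]
    block = getattr(scenario, section)
    value = getattr(block, field) * (1.0 + rel_step)
    new_block = block.model_copy(update={field: value})
    return scenario.model_copy(update={section: new_block})
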