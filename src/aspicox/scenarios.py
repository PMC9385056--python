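"""Scenario parameterisations and precision-dosing experiments.

Three packaged conditions:

* ``healthy`` — physiological megakaryopoiesis and platelet turnover;
* ``ET`` — essential thrombocythemia: accelerated platelet production.
  Relative to healthy it differs in exactly three respects: a shorter MK
  lifetime (the whole MK stage is compressed), increased COX-1 expression in
  MKs, and a maximal acetylation flux increased in proportion to the
  platelet count;
* ``obese`` — severe obesity: identical biology, but systemic aspirin
  bioavailability ``F`` reduced (default 20%).

On top of the scenarios this module runs the dose-grid experiments
(od/bid/tid schedules across doses), generates synthetic sparse sTXB2
observations, and infers bioavailability from such observations by grid
search.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker import ConversionCurve, FeatureSet, extract_features
from .params import PopulationConfig, Regimen, Scenario
from .population import PopulationTrajectory, simulate_regimen

__all__ = [
    "healthy_scenario",
    "et_scenario",
    "obese_scenario",
    "get_scenario",
    "scenario_diff",
    "run_dose_grid",
    "DoseResponseTable",
    "ObservationSeries",
    "generate_observations",
    "infer_bioavailability",
    "stxb2_trajectory",
]


def healthy_scenario(**population_overrides) -> Scenario:
    """The packaged healthy-subject parameterisation."""
    from .io import packaged_scenario
    sc = packaged_scenario("healthy")
    if population_overrides:
        sc = sc.model_copy(update={
            "population": sc.population.model_copy(update=population_overrides)})
    return sc


def et_scenario(**population_overrides) -> Scenario:
    """Essential thrombocythemia (accelerated platelet turnover)."""
    from .io import packaged_scenario
    sc = packaged_scenario("et")
    if population_overrides:
        sc = sc.model_copy(update={
            "population": sc.population.model_copy(update=population_overrides)})
    return sc


def obese_scenario(F: float = 0.2, **population_overrides) -> Scenario:
    """Severe obesity: healthy biology with reduced bioavailability ``F``."""
    from .io import packaged_scenario
    sc = packaged_scenario("obese")
    sc = sc.model_copy(update={"pk": sc.pk.model_copy(update={"F": F})})
    if population_overrides:
        sc = sc.model_copy(update={
            "population": sc.population.model_copy(update=population_overrides)})
    return sc


def get_scenario(label: str, **kw) -> Scenario:
    builders = {"healthy": healthy_scenario, "ET": et_scenario, "et": et_scenario,
                "obese": obese_scenario}
    if label not in builders:
        raise KeyError(f"unknown scenario '{label}'; choose from {sorted(builders)}")
    return builders[label](**kw)


def scenario_diff(a: Scenario, b: Scenario) -> dict[str, tuple[float, float]]:
    """Machine-readable diff of two scenarios: {section.field: (a, b)}.

    Only numeric parameter fields are compared (labels/notes are ignored), so
    the documented minimality of the ET and obese scenarios is auditable.
    """
    out: dict[str, tuple[float, float]] = {}
    for section in ("pk", "pd", "unit", "population"):
        da = getattr(a, section).model_dump()
        db = getattr(b, section).model_dump()
        for key in da:
            if isinstance(da[key], (int, float)) and da[key] != db[key]:
                out[f"{section}.{key}"] = (da[key], db[key])
    return out


# -- dose-grid experiments ---------------------------------------------------

@dataclass
class DoseResponseTable:
    """Features + steady-state sTXB2 for every (dose, schedule) cell."""

    table: pd.DataFrame
    trajectories: dict[tuple[float, str], PopulationTrajectory] = field(default_factory=dict)

    def row(self, dose: float, schedule: str) -> pd.Series:
        df = self.table
        hit = df[(df.dose_mg == dose) & (df.schedule == schedule)]
        if hit.empty:
            raise KeyError(f"no cell for {dose} mg {schedule}")
        return hit.iloc[0]


def _steady_state_stxb2(traj: PopulationTrajectory, curve: ConversionCurve
                        ) -> tuple[float, float, float]:
    """(mean, nadir, peak) sTXB2 [% baseline] over the last full dosing interval."""
    reg = traj.regimen
    lo, hi = reg.last_dose, reg.last_dose + reg.interval
    mask = (traj.t >= lo) & (traj.t <= hi)
    s = curve(np.clip(traj.X_percent[mask], 0.0, 100.0))
    return float(s.mean()), float(s.min()), float(s.max())


def run_dose_grid(scenario: Scenario, doses, schedules, weeks: float = 3.0, *,
                  config: PopulationConfig | None = None,
                  curve: ConversionCurve | None = None,
                  reference: Scenario | None = None,
                  keep_trajectories: bool = False) -> DoseResponseTable:
    """Simulate every dose x schedule cell and tabulate features and sTXB2.

    When ``reference`` is given (e.g. the healthy scenario for an ET grid), a
    reference row labelled schedule ``od_reference`` with 100 mg od is
    appended — the benchmark regimen against which precision dosing is
    judged.
    """
    curve = curve or ConversionCurve()
    rows = []
    trajs: dict[tuple[float, str], PopulationTrajectory] = {}

    def one(sc: Scenario, dose: float, schedule: str, tag: str) -> None:
        reg = Regimen.from_schedule(dose, schedule, days=weeks * 7)
        traj = simulate_regimen(reg, sc, config)
        feats = extract_features(traj)
        mean_s, nadir_s, peak_s = _steady_state_stxb2(traj, curve)
        rows.append({"scenario": sc.label, "dose_mg": dose, "schedule": tag,
                     "daily_dose_mg": reg.daily_dose,
                     **feats.as_dict(),
                     "stxb2_mean_ss": mean_s, "stxb2_nadir_ss": nadir_s,
                     "stxb2_peak_ss": peak_s})
        if keep_trajectories:
            trajs[(dose, tag)] = traj

    for schedule in schedules:
        for dose in doses:
            one(scenario, float(dose), schedule, schedule)
    if reference is not None:
        one(reference, 100.0, "od", "od_reference")
    return DoseResponseTable(table=pd.DataFrame(rows), trajectories=trajs)


# -- synthetic observations & bioavailability inference ----------------------

@dataclass
class ObservationSeries:
    """Sparse sTXB2 measurements: (time [h], % of baseline) with noise sd."""

    times: np.ndarray
    values: np.ndarray
    noise_sd: float
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("sTXB2 values must be nonnegative")


def stxb2_trajectory(traj: PopulationTrajectory,
                     curve: ConversionCurve | None = None) -> np.ndarray:
    """Pointwise sTXB2 [% of baseline] along a trajectory."""
    curve = curve or ConversionCurve()
    return curve(np.clip(traj.X_percent, 0.0, 100.0))


def generate_observations(scenario: Scenario, regimen: Regimen,
                          sample_times, noise_sd: float, seed: int, *,
                          config: PopulationConfig | None = None,
                          curve: ConversionCurve | None = None) -> ObservationSeries:
    """Sample the simulated sTXB2 profile with multiplicative Gaussian noise.

    ``value = profile * (1 + eps)``, ``eps ~ N(0, noise_sd)``, clipped at 0;
    reproducible through ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    sample_times = np.asarray(sample_times, dtype=float)
    traj = simulate_regimen(regimen, scenario, config)
    if sample_times.min() < traj.t[0] or sample_times.max() > traj.t[-1]:
        raise ValueError("sample times fall outside the simulated window")
    curve = curve or ConversionCurve()
    profile = curve(np.clip(traj.sample_percent(sample_times), 0.0, 100.0))
    rng = np.random.default_rng(seed)
    noisy = profile * (1.0 + noise_sd * rng.standard_normal(profile.shape))
    return ObservationSeries(times=sample_times, values=np.clip(noisy, 0.0, None),
                             noise_sd=noise_sd)


@dataclass
class BioavailabilityFit:
    """Grid-search result of the bioavailability inference."""

    F_best: float
    sse: dict[float, float]                      # residual sum of squares per F
    profiles: pd.DataFrame                       # time_h + one sTXB2 column per F

    def as_dict(self) -> dict:
        return {"F_best": self.F_best,
                "sse": {f"{k:g}": v for k, v in self.sse.items()}}


def infer_bioavailability(obs: ObservationSeries, scenario: Scenario,
                          regimen: Regimen, F_grid=None, *,
                          config: PopulationConfig | None = None,
                          curve: ConversionCurve | None = None) -> BioavailabilityFit:
    """Find the bioavailability whose predicted sTXB2 profile best fits ``obs``.

    One whole-body simulation per candidate ``F`` (default grid 0.1..1.0 in
    steps of 0.1); unweighted least squares on the sTXB2 percent scale.
    """
    if obs.times.size < 2:
        raise ValueError("need at least two observations")
    F_grid = np.round(np.arange(0.1, 1.0001, 0.1), 10) if F_grid is None \
        else np.asarray(F_grid, dtype=float)
    curve = curve or ConversionCurve()
    sse: dict[float, float] = {}
    cols = {}
    for F in F_grid:
        sc = scenario.model_copy(update={"pk": scenario.pk.model_copy(update={"F": float(F)})})
        traj = simulate_regimen(regimen, sc, config)
        if obs.times.min() < traj.t[0] or obs.times.max() > traj.t[-1]:
            raise ValueError("observations fall outside the simulated window")
        pred = curve(np.clip(traj.sample_percent(obs.times), 0.0, 100.0))
        sse[float(F)] = float(np.sum((pred - obs.values) ** 2))
        dense = curve(np.clip(traj.X_percent, 0.0, 100.0))
        cols[f"F_{F:g}"] = dense
        t_dense = traj.t
    profiles = pd.DataFrame({"time_h": t_dense, **cols})
    F_best = min(sse, key=sse.get)
    return BioavailabilityFit(F_best=F_best, sse=sse, profiles=profiles)
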