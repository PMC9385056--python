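"""Declarative, re-runnable versions of the packaged in-silico experiments.

Each experiment id maps to one study design: single-unit dose responses,
whole-body trajectories for different schedules, dose grids in healthy and
essential-thrombocythemia conditions, bioavailability inference in obesity
with synthetic observations, and the two sensitivity studies.  Every
experiment writes deterministic CSV tables plus a manifest.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .biomarker import ConversionCurve, extract_features
from .io import RunManifest, frame_to_csv, trajectory_to_csv
from .params import Regimen
from .pk import solve_pk
from .population import simulate_regimen
from .scenarios import (et_scenario, generate_observations, healthy_scenario,
                        infer_bioavailability, obese_scenario, run_dose_grid,
                        stxb2_trajectory)
from .sensitivity import SensitivityConfig, analyze_scenario
from .units import regimen_over_unit_life, solve_units_fast

EXPERIMENTS = [f"fig{i}" for i in range(2, 11)]

# birth phases (unit age at first dose, as a fraction of the unit lifespan)
# used for the four-unit single-dose panel
_SINGLE_DOSE_PHASES = (0.02, 0.15, 0.33, 0.55)


def _single_unit_table(scenario, regimens: list[tuple[float, float]],
                       ds: float = 0.1) -> pd.DataFrame:
    """Unit-lifetime fraction trajectories for each (dose, interval)."""
    frames = []
    for dose, interval in regimens:
        unit = scenario.unit
        reg = regimen_over_unit_life(unit, dose, interval)
        pk = solve_pk(scenario.pk, reg, 0.0, unit.span + 1.0,
                      dt=scenario.population.pk_dt)
        traj = solve_units_fast(np.array([0.0]), unit, scenario.pd, pk, ds)
        frames.append(pd.DataFrame({
            "age_h": traj.s,
            "mk_percent": traj.mk_fraction(0),
            "platelet_percent": traj.platelet_fraction(0),
            "dose_mg": dose, "interval_h": interval,
        }))
    return pd.concat(frames, ignore_index=True)


def reproduce(figure: str, out_dir: Path, n_units: int = 500) -> list[Path]:
    """Run one packaged experiment; returns the written files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    healthy = healthy_scenario(n_units=n_units)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame_to_csv(df, path)
        written.append(path)

    if figure == "fig2":
        reg = Regimen.from_schedule(100.0, "od")
        traj = simulate_regimen(reg, healthy)
        path = out_dir / "healthy_100od_trajectory.csv"
        trajectory_to_csv(traj, path)
        written.append(path)
        feats = extract_features(traj)
        emit(pd.DataFrame([feats.as_dict()]), "healthy_100od_features.csv")
        RunManifest.for_run(healthy, reg, [str(p) for p in written]).write(
            out_dir / "manifest.json")

    elif figure == "fig3":
        unit = healthy.unit
        rows = []
        for phase in _SINGLE_DOSE_PHASES:
            t_dose = phase * unit.span
            reg = Regimen(dose=100.0, interval=24.0, n_doses=1, start=t_dose)
            pk = solve_pk(healthy.pk, reg, 0.0, unit.span + 1.0,
                          dt=healthy.population.pk_dt)
            traj = solve_units_fast(np.array([0.0]), unit, healthy.pd, pk, 0.1)
            rows.append(pd.DataFrame({
                "age_h": traj.s,
                "mk_percent": traj.mk_fraction(0),
                "platelet_percent": traj.platelet_fraction(0),
                "dose_age_h": t_dose,
            }))
        emit(pd.concat(rows, ignore_index=True), "single_dose_four_units.csv")

    elif figure == "fig4":
        df = _single_unit_table(
            healthy, [(100.0, 24.0), (200.0, 24.0), (50.0, 12.0), (100.0, 12.0)])
        emit(df, "single_unit_regimens.csv")

    elif figure == "fig5":
        reg = Regimen.from_schedule(100.0, "od")
        small = healthy_scenario(n_units=max(8, min(32, n_units)))
        traj = simulate_regimen(reg, small, keep_units=True)
        u = traj.units
        frames = []
        for i in range(u.tau.size):
            frames.append(pd.DataFrame({
                "time_h": u.tau[i] + u.s,
                "unit": i,
                "mk_percent": u.mk_fraction(i),
                "platelet_percent": u.platelet_fraction(i),
            }))
        emit(pd.concat(frames, ignore_index=True), "multi_unit_overlay.csv")

    elif figure == "fig6":
        tab = run_dose_grid(healthy, [25.0, 50.0, 100.0, 200.0], ["od", "bid"])
        emit(tab.table, "healthy_dose_grid.csv")

    elif figure == "fig7":
        et = et_scenario(n_units=n_units)
        tab = run_dose_grid(et, [25.0, 50.0, 100.0, 200.0], ["od", "bid", "tid"],
                            reference=healthy)
        emit(tab.table, "et_dose_grid.csv")

    elif figure == "fig8":
        obese = obese_scenario(F=0.2, n_units=n_units)
        reg = Regimen.from_schedule(100.0, "od", days=14)
        times = 24.0 * np.arange(1.0, 14.0, 2.0) - 1.0
        obs = generate_observations(obese, reg, times, noise_sd=0.05, seed=20220817)
        fit = infer_bioavailability(obs, obese_scenario(F=1.0, n_units=n_units), reg)
        emit(pd.DataFrame({"time_h": obs.times, "stxb2_percent": obs.values}),
             "obese_observations.csv")
        emit(fit.profiles, "bioavailability_profiles.csv")
        emit(pd.DataFrame([{"F_best": fit.F_best, **{f"sse_F{k:g}": v
                                                     for k, v in fit.sse.items()}}]),
             "bioavailability_fit.csv")

    elif figure in ("fig9", "fig10"):
        reg = Regimen.from_schedule(100.0, "od")
        for sc in (healthy, et_scenario(n_units=n_units)):
            res = analyze_scenario(sc, reg, SensitivityConfig())
            emit(res.index_table(), f"sensitivity_{sc.label}.csv")

    else:
        raise KeyError(f"unknown experiment '{figure}'; valid ids: {EXPERIMENTS}")

    return written
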