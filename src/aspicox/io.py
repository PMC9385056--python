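"""Configuration loading, result serialisation and run manifests.

Scenario files are YAML with an explicit units header; trajectories are tidy
CSV; manifests are JSON sidecars carrying everything needed to re-run an
experiment exactly (parameters checksum, solver settings, package version).
"""
from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__
from .params import (PDParameters, PKParameters, PopulationConfig, Regimen,
                     Scenario, UnitParameters)
from .population import PopulationTrajectory

__all__ = [
    "load_config",
    "save_config",
    "packaged_scenario",
    "parameter_checksum",
    "trajectory_to_csv",
    "RunManifest",
]

UNITS_HEADER = {
    "time": "hours",
    "drug_amount": "mg",
    "concentration": "mg/L",
    "cox1": "arbitrary units (percent of total where stated)",
}


def _scenario_from_mapping(data: dict) -> Scenario:
    try:
        return Scenario(
            label=data["label"],
            pk=PKParameters(**data["pk"]),
            pd=PDParameters(**data["pd"]),
            unit=UnitParameters(**data["unit"]),
            population=PopulationConfig(**data.get("population", {})),
            notes=data.get("notes", {}),
        )
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(
            f"invalid scenario configuration: field '{loc}' {first['msg']}"
        ) from err


def load_config(path: str | Path) -> Scenario:
    """Load and validate a scenario YAML; errors name the offending field."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: not a mapping")
    return _scenario_from_mapping(data)


def save_config(scenario: Scenario, path: str | Path) -> None:
    data = {
        "label": scenario.label,
        "units": dict(UNITS_HEADER),
        "pk": scenario.pk.model_dump(),
        "pd": scenario.pd.model_dump(),
        "unit": scenario.unit.model_dump(),
        "population": scenario.population.model_dump(),
        "notes": dict(scenario.notes),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def packaged_scenario(label: str) -> Scenario:
    """Load one of the scenario files shipped with the package."""
    ref = resources.files("aspicox.data").joinpath(f"{label}.yaml")
    if not ref.is_file():
        available = sorted(p.name[:-5] for p in resources.files("aspicox.data").iterdir()
                           if p.name.endswith(".yaml"))
        raise KeyError(f"unknown scenario '{label}'; packaged scenarios: {available}")
    data = yaml.safe_load(ref.read_text())
    return _scenario_from_mapping(data)


def parameter_checksum(scenario: Scenario) -> str:
    """SHA-256 over the canonical JSON of every parameter in the scenario."""
    payload = {
        "label": scenario.label,
        "pk": scenario.pk.model_dump(),
        "pd": scenario.pd.model_dump(),
        "unit": scenario.unit.model_dump(),
        "population": scenario.population.model_dump(),
    }
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def trajectory_to_csv(traj: PopulationTrajectory, path: str | Path,
                      long_format: bool = False) -> None:
    """Write a trajectory as CSV: wide by default, or tidy long format
    (columns time, compartment, quantity, value)."""
    df = traj.to_frame()
    if long_format:
        df = df.melt(id_vars="time_h", var_name="quantity", value_name="value")
        df.insert(1, "compartment", df["quantity"].map({
            "X_percent": "circulating_platelets",
            "X_amount_au": "circulating_platelets",
            "A_B_mg": "systemic_blood",
        }))
    df.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Reproducibility sidecar of one experiment run."""

    scenario_label: str
    regimen: str
    n_units: int
    parameter_checksum: str
    outputs: list[str] = field(default_factory=list)
    solver: dict = field(default_factory=dict)
    code_version: str = ""
    created: str = ""

    @classmethod
    def for_run(cls, scenario: Scenario, regimen: Regimen,
                outputs: list[str] | None = None,
                solver: dict | None = None) -> "RunManifest":
        return cls(
            scenario_label=scenario.label,
            regimen=regimen.label,
            n_units=scenario.population.n_units,
            parameter_checksum=parameter_checksum(scenario),
            outputs=outputs or [],
            solver=solver or {"pk_dt": scenario.population.pk_dt,
                              "dt_target": scenario.population.dt_target},
            code_version=__version__,
            created=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def features_to_json(features, path: str | Path) -> None:
    """Write a FeatureSet as JSON with the canonical keys and units note."""
    payload = dict(features.as_dict())
    payload["units"] = {"X_ss": "%", "X1": "%", "X2": "%", "PP": "%",
                        "D1": "-", "D": "-", "Tr": "h"}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def frame_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
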