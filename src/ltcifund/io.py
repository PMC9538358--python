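"""Configuration and report I/O.

Config files are YAML (JSON parses as YAML) with sections base_year,
horizon, populations, bases, growth, schedule, care_cost and
initial_balance; every invariant is checked at load time and violations
name the offending field.  Trajectory CSVs round-trip at full float
precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .calibration import ValidationReport
from .model import FundTrajectory
from .params import (
    ConfigError,
    ContributionSchedule,
    EconomicState,
    GroupContribution,
    GrowthRates,
    ParameterSet,
    PopulationState,
    GROUPS,
)
from .scenarios import GridResults

__all__ = [
    "RunConfig", "load_config", "dump_config", "params_to_dict",
    "write_trajectory_csv", "read_trajectory_csv",
    "write_table_csv", "write_envelope_csv",
    "read_historical_csv", "write_historical_csv",
]

_TOP_KEYS = {"base_year", "horizon", "populations", "bases", "growth", "schedule",
             "care_cost", "initial_balance", "retirement_flow_rate",
             "disability_base", "run"}
_RUN_KEYS = {"unit", "output_dir", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """Reporting options carried alongside the parameters."""

    unit: float = 1e9
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.unit <= 0:
            raise ConfigError(f"run.unit: must be > 0, got {self.unit}")


def _section(data: Mapping, name: str, required: bool = True) -> Mapping:
    if name not in data:
        if required:
            raise ConfigError(f"{name}: missing required section")
        return {}
    sec = data[name]
    if not isinstance(sec, Mapping):
        raise ConfigError(f"{name}: expected a mapping, got {type(sec).__name__}")
    return sec


def _get(sec: Mapping, section: str, key: str, default=None, required: bool = False):
    if key not in sec:
        if required:
            raise ConfigError(f"{section}.{key}: missing required field")
        return default
    return sec[key]


def load_config(path) -> tuple[ParameterSet, RunConfig]:
    """Parse and fully validate a config file.

    Unknown keys, missing required fields and invariant violations all
    raise :class:`ConfigError` naming the field.  An omitted horizon
    defaults to 2020-2050.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config: file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config: cannot parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError("config: top level must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")

    base_year = int(data.get("base_year", 2019))
    horizon = data.get("horizon", [base_year + 1, 2050])
    if not (isinstance(horizon, (list, tuple)) and len(horizon) == 2):
        raise ConfigError("horizon: expected [start, end]")
    pops = _section(data, "populations")
    bases = _section(data, "bases")
    growth = _section(data, "growth", required=False)
    for key in pops.keys() - {"employees", "retirees", "residents"}:
        raise ConfigError(f"populations.{key}: unknown group")
    for key in bases.keys() - {"wage", "pension", "resident_income"}:
        raise ConfigError(f"bases.{key}: unknown base")
    known_growth = {"employees", "retirees", "residents", "wage", "pension",
                    "resident_income", "care_cost"}
    for key in growth.keys() - known_growth:
        raise ConfigError(f"growth.{key}: unknown rate")

    population = PopulationState(
        base_year,
        float(_get(pops, "populations", "employees", required=True)),
        float(_get(pops, "populations", "retirees", required=True)),
        float(_get(pops, "populations", "residents", required=True)))
    economy = EconomicState(
        base_year,
        wage_base=float(_get(bases, "bases", "wage", required=True)),
        pension_base=float(_get(bases, "bases", "pension", required=True)),
        resident_income_base=float(_get(bases, "bases", "resident_income", required=True)),
        care_cost=float(_get(data, "config", "care_cost", required=True)))
    care_growth = growth.get("care_cost")
    rates = GrowthRates(
        employees=float(growth.get("employees", 0.0)),
        retirees=float(growth.get("retirees", 0.0)),
        residents=float(growth.get("residents", 0.0)),
        wage=float(growth.get("wage", 0.0)),
        pension=float(growth.get("pension", 0.0)),
        resident_income=float(growth.get("resident_income", 0.0)),
        care_cost=None if care_growth is None else float(care_growth))

    sched_sec = _section(data, "schedule", required=False)
    groups = {}
    for g in GROUPS:
        gsec = sched_sec.get(g, {})
        if not isinstance(gsec, Mapping):
            raise ConfigError(f"schedule.{g}: expected a mapping")
        for key in gsec.keys() - {"individual", "employer", "government"}:
            raise ConfigError(f"schedule.{g}.{key}: unknown multiplier")
        groups[g] = GroupContribution(
            individual=float(gsec.get("individual", 1.0)),
            employer=float(gsec.get("employer", 0.0)),
            government=float(gsec.get("government", 0.0)))
    schedule = ContributionSchedule(**groups)

    params = ParameterSet(
        base_year=base_year,
        horizon=(int(horizon[0]), int(horizon[1])),
        initial_population=population,
        initial_economy=economy,
        growth=rates,
        schedule=schedule,
        initial_balance=float(data.get("initial_balance", 0.0)),
        retirement_flow_rate=float(data.get("retirement_flow_rate", 0.0)),
        disability_base=str(data.get("disability_base", "total")))

    run_sec = _section(data, "run", required=False)
    for key in run_sec.keys() - _RUN_KEYS:
        raise ConfigError(f"run.{key}: unknown option")
    run = RunConfig(unit=float(run_sec.get("unit", 1e9)),
                    output_dir=str(run_sec.get("output_dir", ".")),
                    log_level=str(run_sec.get("log_level", "INFO")))
    return params, run


def params_to_dict(params: ParameterSet, run: RunConfig | None = None) -> dict:
    p, e, g = params.initial_population, params.initial_economy, params.growth
    out = {
        "base_year": params.base_year,
        "horizon": list(params.horizon),
        "populations": {"employees": p.insured_employees,
                        "retirees": p.insured_retirees,
                        "residents": p.insured_residents},
        "bases": {"wage": e.wage_base, "pension": e.pension_base,
                  "resident_income": e.resident_income_base},
        "care_cost": e.care_cost,
        "growth": {"employees": g.employees, "retirees": g.retirees,
                   "residents": g.residents, "wage": g.wage, "pension": g.pension,
                   "resident_income": g.resident_income,
                   **({"care_cost": g.care_cost} if g.care_cost is not None else {})},
        "schedule": {
            name: {"individual": gc.individual, "employer": gc.employer,
                   "government": gc.government}
            for name, gc in ((n, params.schedule.for_group(n)) for n in GROUPS)},
        "initial_balance": params.initial_balance,
        "retirement_flow_rate": params.retirement_flow_rate,
        "disability_base": params.disability_base,
    }
    if run is not None:
        out["run"] = {"unit": run.unit, "output_dir": run.output_dir,
                      "log_level": run.log_level}
    return out


def dump_config(params: ParameterSet, path, run: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params, run), fh, sort_keys=False)


def config_hash(params: ParameterSet) -> str:
    """Short digest of a parameter world, recorded in logs for
    reproducibility."""
    blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# tabular outputs


def write_trajectory_csv(traj: FundTrajectory, path, unit: float = 1.0,
                         scheme_id: str | None = None) -> None:
    """Tidy CSV: year, revenue, expenditure, balance, scheme_id, unit.
    Values round-trip at full float precision."""
    df = traj.to_frame(unit=unit)
    df["scheme_id"] = scheme_id if scheme_id is not None else traj.scheme.label()
    df["unit"] = unit
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = {"year", "revenue", "expenditure", "balance", "scheme_id", "unit"}
    missing = expected - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory csv: missing columns {sorted(missing)}")
    return df


def write_table_csv(results: GridResults, path, unit: float = 1e9) -> None:
    """Published-layout table of the appropriate schemes."""
    results.selection_table(unit=unit).to_csv(path, index=False)


def write_envelope_csv(result, path, unit: float = 1.0) -> None:
    env = result.envelope.copy()
    for col in env.columns:
        if col != "year":
            env[col] = env[col] / unit
    env.to_csv(path, index=False)


def write_historical_csv(series: Mapping[str, pd.Series], path) -> None:
    """Observed-series CSV with columns year, value, series_label."""
    rows = []
    for label, s in series.items():
        for year, value in s.items():
            rows.append({"year": int(year), "value": float(value),
                         "series_label": label})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_historical_csv(path) -> dict[str, pd.Series]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"year", "value", "series_label"} - set(df.columns)
    if missing:
        raise ConfigError(f"historical csv: missing columns {sorted(missing)}")
    out = {}
    for label, grp in df.groupby("series_label"):
        out[str(label)] = pd.Series(grp["value"].to_numpy(),
                                    index=grp["year"].to_numpy(dtype=int), name=label)
    return out
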