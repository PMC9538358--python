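"""Synthetic parameter sets and pseudo-historical series.

The package ships no statistical-yearbook data; this module generates
inputs with the statistical structure the analysis assumes.  The
``china_scale`` preset is a forward-designed reconstruction anchored to
published magnitudes: insured populations of hundreds of millions, a
resident-income payment base such that 0.08-0.1% payment rates imply
premiums of roughly 34-43 yuan/person/year, stable growth of wages and
income, and long-term-care cost inflation outpacing income growth so
that fund balances peak in the mid-to-late 2040s.  The ``toy`` preset
is a hand-checkable round-number world.

Pseudo-historical series are model back-casts with small multiplicative
Gaussian noise, emulating yearbook series for the historical test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import LTCIFundModel
from .params import (
    ConfigError,
    ContributionSchedule,
    EconomicState,
    GrowthRates,
    ParameterSet,
    PopulationState,
)

__all__ = ["SyntheticSpec", "default_parameter_set", "gen_historical_series",
           "gen_link_series"]

PRESETS = ("toy", "china_scale")


@dataclass(frozen=True)
class SyntheticSpec:
    """What to generate: preset scale, noise level and historical window."""

    seed: int = 0
    scale_preset: str = "china_scale"
    noise_sd: float = 0.02
    window: tuple[int, int] = (2011, 2019)

    def __post_init__(self) -> None:
        if self.scale_preset not in PRESETS:
            raise ConfigError(f"scale_preset: unknown preset {self.scale_preset!r}; "
                              f"choose from {PRESETS}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.window[0] > self.window[1]:
            raise ConfigError(f"window: start after end in {self.window}")


def _toy_parameter_set() -> ParameterSet:
    # the hand-arithmetic world: 1M insured employees on a 40,000 base,
    # zero growth, care cost 10,000 -> at (0.1%, 0.25%, 0.8) revenue is
    # 40M/yr, expenditure 20M/yr, balance 60M after three years
    return ParameterSet(
        base_year=2019,
        horizon=(2020, 2050),
        initial_population=PopulationState(2019, 1_000_000, 0.0, 0.0),
        initial_economy=EconomicState(2019, wage_base=40_000.0, pension_base=40_000.0,
                                      resident_income_base=40_000.0, care_cost=10_000.0),
        growth=GrowthRates(care_cost=0.0),
        schedule=ContributionSchedule(),
        initial_balance=0.0,
    )


def _china_scale_parameter_set() -> ParameterSet:
    # 2019 magnitudes: ~243M active urban-employee SMI enrollees, ~86M
    # retired enrollees, ~1.025B resident-scheme enrollees; urban wage
    # ~90k, pension ~40k, per-capita disposable income ~42.75k yuan
    # (0.0008..0.001 x 42,750 = 34.2..42.75 yuan/person/year premiums).
    # Care cost 11,400 yuan/yr growing 8%/yr against 6.5% income growth
    # places the (0.08%, 0.3%, 80%) scheme's balance peak in 2046.
    return ParameterSet(
        base_year=2019,
        horizon=(2020, 2050),
        initial_population=PopulationState(2019, 243e6, 86e6, 1025e6),
        initial_economy=EconomicState(2019, wage_base=90_000.0, pension_base=40_000.0,
                                      resident_income_base=42_750.0, care_cost=11_400.0),
        growth=GrowthRates(employees=0.005, retirees=0.03, residents=-0.002,
                           wage=0.065, pension=0.055, resident_income=0.065,
                           care_cost=0.08),
        schedule=ContributionSchedule(),
        initial_balance=0.0,
    )


def default_parameter_set(spec: SyntheticSpec | None = None) -> ParameterSet:
    """The preset parameter world; deterministic given the spec."""
    spec = spec if spec is not None else SyntheticSpec()
    if spec.scale_preset == "toy":
        return _toy_parameter_set()
    return _china_scale_parameter_set()


def _multiplicative_noise(rng: np.random.Generator, size: int, sd: float) -> np.ndarray:
    # truncated at -90% so positive-valued series stay positive
    eps = rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)
    return 1.0 + np.maximum(eps, -0.9)


def gen_historical_series(params: ParameterSet,
                          spec: SyntheticSpec | None = None) -> dict[str, pd.Series]:
    """Pseudo-yearbook series over the historical window.

    Back-casts the model's insured-urban-employee and resident-income
    paths and multiplies each value by (1 + eps), eps ~ N(0, noise_sd)
    truncated at -0.9.  With ``noise_sd=0`` the model path is returned
    exactly, so the historical test passes with zero error.
    """
    spec = spec if spec is not None else SyntheticSpec()
    lo, hi = spec.window
    if hi > params.base_year:
        raise ConfigError(f"window: {spec.window} overlaps the forecast horizon "
                          f"(base year {params.base_year})")
    years = np.arange(lo, hi + 1)
    paths = LTCIFundModel(params).backcast(years)
    rng = np.random.default_rng(spec.seed)
    out: dict[str, pd.Series] = {}
    for label in ("insured_urban_employees", "resident_income"):
        noise = _multiplicative_noise(rng, len(years), spec.noise_sd)
        out[label] = pd.Series(paths[label].to_numpy() * noise, index=years, name=label)
    return out


def gen_link_series(params: ParameterSet, spec: SyntheticSpec | None = None,
                    participation: float = 0.92) -> tuple[pd.Series, pd.Series]:
    """Paired (total urban employees, insured employees) series for
    fitting the employment link: insured = participation x total, with
    multiplicative noise on the insured side."""
    spec = spec if spec is not None else SyntheticSpec()
    lo, hi = spec.window
    if hi > params.base_year:
        raise ConfigError(f"window: {spec.window} overlaps the forecast horizon")
    years = np.arange(lo, hi + 1)
    insured_path = LTCIFundModel(params).backcast(years)["insured_urban_employees"]
    total = insured_path / participation
    rng = np.random.default_rng(spec.seed + 1)
    noise = _multiplicative_noise(rng, len(years), spec.noise_sd)
    insured = pd.Series(insured_path.to_numpy() * noise, index=years,
                        name="insured_urban_employees")
    return pd.Series(total.to_numpy(), index=years, name="urban_employees"), insured
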