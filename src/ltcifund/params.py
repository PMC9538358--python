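"""Parameter containers for the LTCI fund model.

A :class:`ParameterSet` fixes one model world: the base-year insured
populations and payment bases, their growth rates, the contribution
schedule and the opening fund balance.  A :class:`Scheme` carries the
three policy knobs that are varied across financing scenarios: the
individual payment rate, the severe disability rate and the
reimbursement ratio.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "ConfigError",
    "PopulationState",
    "EconomicState",
    "GrowthRates",
    "GroupContribution",
    "ContributionSchedule",
    "ParameterSet",
    "Scheme",
    "GROUPS",
]

#: Insured groups, in the order used throughout the package.
GROUPS = ("employees", "retirees", "residents")


class ConfigError(ValueError):
    """A parameter violates a model invariant; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PopulationState:
    """Insured head counts (persons) in one calendar year.

    ``insured_employees`` are active urban-employee SMI enrollees,
    ``insured_retirees`` retired-employee enrollees and
    ``insured_residents`` urban-and-rural-resident SMI enrollees.
    """

    year: int
    insured_employees: float
    insured_retirees: float
    insured_residents: float

    def __post_init__(self) -> None:
        for name in ("insured_employees", "insured_retirees", "insured_residents"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, name, f"must be a finite count >= 0, got {v}")

    @property
    def total_insured(self) -> float:
        return self.insured_employees + self.insured_retirees + self.insured_residents

    def group(self, name: str) -> float:
        return {
            "employees": self.insured_employees,
            "retirees": self.insured_retirees,
            "residents": self.insured_residents,
        }[name]


@dataclass(frozen=True)
class EconomicState:
    """Per-capita monetary quantities (yuan/person/year) in one year.

    The three payment bases mirror the three revenue subsystems:
    active employees contribute on ``wage_base``, retirees on
    ``pension_base`` and residents on ``resident_income_base``
    (per-capita disposable income).  ``care_cost`` is the annual
    reimbursable long-term-care cost per severely disabled person.
    """

    year: int
    wage_base: float
    pension_base: float
    resident_income_base: float
    care_cost: float

    def __post_init__(self) -> None:
        for name in ("wage_base", "pension_base", "resident_income_base", "care_cost"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, name, f"must be finite and > 0, got {v}")

    def base_for(self, group: str) -> float:
        return {
            "employees": self.wage_base,
            "retirees": self.pension_base,
            "residents": self.resident_income_base,
        }[group]


@dataclass(frozen=True)
class GrowthRates:
    """Annual growth fractions; each must lie in (-1, 1).

    ``care_cost`` may be None, in which case care-cost inflation tracks
    resident income growth.
    """

    employees: float = 0.0
    retirees: float = 0.0
    residents: float = 0.0
    wage: float = 0.0
    pension: float = 0.0
    resident_income: float = 0.0
    care_cost: float | None = None

    def __post_init__(self) -> None:
        for name in ("employees", "retirees", "residents", "wage", "pension", "resident_income"):
            v = getattr(self, name)
            _require(-1.0 < v < 1.0, f"growth.{name}", f"must lie in (-1, 1), got {v}")
        if self.care_cost is not None:
            _require(-1.0 < self.care_cost < 1.0, "growth.care_cost",
                     f"must lie in (-1, 1), got {self.care_cost}")

    @property
    def effective_care_cost(self) -> float:
        return self.resident_income if self.care_cost is None else self.care_cost

    def population(self, group: str) -> float:
        return getattr(self, group)

    def base(self, group: str) -> float:
        return {"employees": self.wage, "retirees": self.pension,
                "residents": self.resident_income}[group]


@dataclass(frozen=True)
class GroupContribution:
    """Multipliers applied to (payment rate x payment base) for one group."""

    individual: float = 1.0
    employer: float = 0.0
    government: float = 0.0

    def __post_init__(self) -> None:
        for name in ("individual", "employer", "government"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"schedule.{name}", f"must be >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.individual + self.employer + self.government


@dataclass(frozen=True)
class ContributionSchedule:
    """Who pays on top of the individual premium, per insured group.

    The default — individual multiplier 1, employer and government 0 —
    models pure individual financing; the multipliers are the hook for
    the individual + enterprise + government design.
    """

    employees: GroupContribution = field(default_factory=GroupContribution)
    retirees: GroupContribution = field(default_factory=GroupContribution)
    residents: GroupContribution = field(default_factory=GroupContribution)

    def for_group(self, group: str) -> GroupContribution:
        return getattr(self, group)


@dataclass(frozen=True)
class Scheme:
    """One financing scheme: the three intervention knobs.

    Rates are fractions, e.g. ``individual_payment_rate=0.0008`` for
    0.08% of the payment base and ``severe_disability_rate=0.003`` for
    0.3% of the insured population.
    """

    individual_payment_rate: float
    severe_disability_rate: float
    reimbursement_ratio: float

    def __post_init__(self) -> None:
        # zero is a meaningful edge (no premium / no beneficiaries / no
        # reimbursement), so the closed interval [0, 1] is accepted here;
        # scenario grids restrict levels to the open interval.
        for name in ("individual_payment_rate", "severe_disability_rate", "reimbursement_ratio"):
            v = getattr(self, name)
            _require(math.isfinite(v) and 0.0 <= v <= 1.0, name,
                     f"must lie in [0, 1], got {v}")

    def label(self) -> str:
        return (f"rate={self.individual_payment_rate:.4%}"
                f"|sdr={self.severe_disability_rate:.4%}"
                f"|reimb={self.reimbursement_ratio:.0%}")


@dataclass(frozen=True)
class ParameterSet:
    """Everything that defines one model world except the scheme.

    horizon is the inclusive forecast range and must start the year
    after ``base_year``.  ``retirement_flow_rate`` > 0 switches the
    population dynamics from independent exponential growth to a flow
    mode in which that fraction of active employees retires each year
    (adding to the retiree pool).  ``disability_base`` selects which
    insured population the severe disability rate applies to.
    """

    base_year: int = 2019
    horizon: tuple[int, int] = (2020, 2050)
    initial_population: PopulationState = field(
        default_factory=lambda: PopulationState(2019, 0.0, 0.0, 0.0))
    initial_economy: EconomicState = field(
        default_factory=lambda: EconomicState(2019, 1.0, 1.0, 1.0, 1.0))
    growth: GrowthRates = field(default_factory=GrowthRates)
    schedule: ContributionSchedule = field(default_factory=ContributionSchedule)
    initial_balance: float = 0.0
    retirement_flow_rate: float = 0.0
    disability_base: str = "total"

    def __post_init__(self) -> None:
        start, end = self.horizon
        _require(start == self.base_year + 1, "horizon",
                 f"must start at base_year + 1 = {self.base_year + 1}, got {start}")
        _require(end >= start, "horizon", f"end {end} precedes start {start}")
        _require(self.initial_population.year == self.base_year, "initial_population.year",
                 f"must equal base_year {self.base_year}")
        _require(self.initial_economy.year == self.base_year, "initial_economy.year",
                 f"must equal base_year {self.base_year}")
        _require(math.isfinite(self.initial_balance), "initial_balance", "must be finite")
        _require(0.0 <= self.retirement_flow_rate < 1.0, "retirement_flow_rate",
                 f"must lie in [0, 1), got {self.retirement_flow_rate}")
        _require(self.disability_base in ("total",) + GROUPS, "disability_base",
                 f"must be 'total' or one of {GROUPS}, got {self.disability_base!r}")

    @property
    def horizon_years(self) -> range:
        return range(self.horizon[0], self.horizon[1] + 1)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def __iter__(self) -> Iterator[int]:  # convenience: iterate forecast years
        return iter(self.horizon_years)
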