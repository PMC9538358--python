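"""The stock-flow engine.

The fund balance is the single stock; annual revenue and expenditure are
the flows.  Revenue is premium income summed over the three insured
groups (active employees on wages, retirees on pensions, residents on
per-capita disposable income); expenditure is the reimbursed care cost
of the severely disabled share of the insured pool.  The stock update is
Euler with an annual step: balance(t) = balance(t-1) + revenue(t) -
expenditure(t).

:class:`LTCIFundModel` is the model object built from a
:class:`~ltcifund.params.ParameterSet`; ``simulate(scheme)`` returns a
:class:`FundTrajectory` results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    GROUPS,
    ConfigError,
    ContributionSchedule,
    EconomicState,
    ParameterSet,
    PopulationState,
    Scheme,
)

__all__ = [
    "LTCIFundModel",
    "FundTrajectory",
    "project_population",
    "project_economy",
    "severely_disabled_count",
    "annual_revenue",
    "annual_expenditure",
    "step_balance",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# elementary operations


def severely_disabled_count(pop: PopulationState, scheme: Scheme,
                            disability_base: str = "total") -> float:
    """Expected number of LTCI beneficiaries in one year.

    The severe disability rate applies to the total insured pool by
    default (``disability_base='total'``) or to a single group.  The
    count is real-valued: the model does expected-value accounting and
    never rounds person counts.
    """
    if disability_base == "total":
        base = pop.total_insured
    else:
        base = pop.group(disability_base)
    return scheme.severe_disability_rate * base


def annual_revenue(pop: PopulationState, econ: EconomicState, scheme: Scheme,
                   schedule: ContributionSchedule | None = None) -> float:
    """Premium income (yuan) for one year.

    revenue = sum over groups of
        insured_g * base_g * rate * (individual + employer + government),
    hence exactly linear in the individual payment rate.
    """
    schedule = schedule if schedule is not None else ContributionSchedule()
    rate = scheme.individual_payment_rate
    total = 0.0
    for g in GROUPS:
        total += pop.group(g) * econ.base_for(g) * rate * schedule.for_group(g).total
    return total


def annual_expenditure(pop: PopulationState, econ: EconomicState, scheme: Scheme,
                       disability_base: str = "total") -> float:
    """Reimbursed care spending (yuan) for one year:
    beneficiaries * care_cost * reimbursement_ratio."""
    n = severely_disabled_count(pop, scheme, disability_base)
    return n * econ.care_cost * scheme.reimbursement_ratio


def step_balance(prev_balance: float, revenue: float, expenditure: float) -> float:
    """One Euler step of the stock: cumulative value = previous value
    plus the net flow.  Deficits (negative balances) are meaningful and
    are never clipped."""
    for name, v in (("prev_balance", prev_balance), ("revenue", revenue),
                    ("expenditure", expenditure)):
        if not math.isfinite(v):
            raise ConfigError(f"{name}: must be finite, got {v}")
    return prev_balance + revenue - expenditure


# ---------------------------------------------------------------------------
# projections


def _check_count(value: float, group: str, year: int) -> float:
    if not math.isfinite(value) or value < 0:
        raise ConfigError(
            f"initial_population.{group}: growth configuration projects an "
            f"invalid count {value} in {year}")
    return value


def project_population(params: ParameterSet, years: Sequence[int] | None = None,
                       employees_override: Mapping[int, float] | Callable[[int], float] | None = None,
                       ) -> list[PopulationState]:
    """Project insured head counts over ``years`` (default: the horizon).

    Default mode: each group compounds independently, group(t) =
    group(base) * (1 + g)^(t - base_year); negative exponents back-cast
    years before the base.  If ``retirement_flow_rate`` > 0, a flow mode
    is used instead: each year that fraction of active employees moves
    to the retiree pool on top of the groups' own growth (forecast
    years only; flow mode cannot back-cast).

    ``employees_override`` (a year->count mapping or callable), when
    given, replaces the insured-employees path — the hook for the
    regression link to total urban employees fitted in
    :mod:`ltcifund.calibration`.
    """
    if years is None:
        years = list(params.horizon_years)
    years = list(years)
    if not years:
        raise ConfigError("horizon: no years to project")
    p0, g = params.initial_population, params.growth
    flow = params.retirement_flow_rate

    def override(year: int) -> float | None:
        if employees_override is None:
            return None
        if callable(employees_override):
            return float(employees_override(year))
        return float(employees_override[year]) if year in employees_override else None

    out: list[PopulationState] = []
    if flow > 0.0:
        if min(years) <= params.base_year:
            raise ConfigError("retirement_flow_rate: flow mode cannot back-cast "
                              "years at or before the base year")
        emp, ret = p0.insured_employees, p0.insured_retirees
        state_year = params.base_year
        states: dict[int, tuple[float, float]] = {}
        for year in range(params.base_year + 1, max(years) + 1):
            retiring = flow * emp
            emp = emp * (1.0 + g.employees) - retiring
            ret = ret * (1.0 + g.retirees) + retiring
            states[year] = (emp, ret)
            state_year = year
        for year in years:
            emp_y, ret_y = states[year]
            res_y = p0.insured_residents * (1.0 + g.residents) ** (year - params.base_year)
            ov = override(year)
            out.append(PopulationState(
                year,
                _check_count(ov if ov is not None else emp_y, "insured_employees", year),
                _check_count(ret_y, "insured_retirees", year),
                _check_count(res_y, "insured_residents", year)))
        return out

    for year in years:
        dt = year - params.base_year
        emp = p0.insured_employees * (1.0 + g.employees) ** dt
        ov = override(year)
        out.append(PopulationState(
            year,
            _check_count(ov if ov is not None else emp, "insured_employees", year),
            _check_count(p0.insured_retirees * (1.0 + g.retirees) ** dt,
                         "insured_retirees", year),
            _check_count(p0.insured_residents * (1.0 + g.residents) ** dt,
                         "insured_residents", year)))
    return out


def project_economy(params: ParameterSet,
                    years: Sequence[int] | None = None) -> list[EconomicState]:
    """Compound each monetary base at its configured rate; strictly
    positive throughout (negative exponents back-cast)."""
    if years is None:
        years = list(params.horizon_years)
    years = list(years)
    if not years:
        raise ConfigError("horizon: no years to project")
    e0, g = params.initial_economy, params.growth
    out = []
    for year in years:
        dt = year - params.base_year
        out.append(EconomicState(
            year,
            wage_base=e0.wage_base * (1.0 + g.wage) ** dt,
            pension_base=e0.pension_base * (1.0 + g.pension) ** dt,
            resident_income_base=e0.resident_income_base * (1.0 + g.resident_income) ** dt,
            care_cost=e0.care_cost * (1.0 + g.effective_care_cost) ** dt,
        ))
    return out


# ---------------------------------------------------------------------------
# trajectory results object


@dataclass(frozen=True)
class FundTrajectory:
    """Year-indexed revenue, expenditure and cumulative balance (yuan)
    for one scheme; the results object returned by
    :meth:`LTCIFundModel.simulate`."""

    years: np.ndarray
    revenue: np.ndarray
    expenditure: np.ndarray
    balance: np.ndarray
    scheme: Scheme
    initial_balance: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.revenue) == len(self.expenditure) == len(self.balance) == n):
            raise ConfigError("trajectory: series lengths differ")
        if n == 0:
            raise ConfigError("trajectory: empty horizon")

    # -- diagnostics -------------------------------------------------------

    @property
    def terminal_balance(self) -> float:
        return float(self.balance[-1])

    @property
    def peak_index(self) -> int:
        # latest year attaining the maximum (ties break late)
        b = self.balance
        return int(len(b) - 1 - np.argmax(b[::-1]))

    @property
    def peak_year(self) -> int:
        return int(self.years[self.peak_index])

    @property
    def peak_value(self) -> float:
        return float(self.balance[self.peak_index])

    @property
    def first_deficit_year(self) -> int | None:
        idx = np.nonzero(self.balance < 0.0)[0]
        return int(self.years[idx[0]]) if idx.size else None

    def to_frame(self, unit: float = 1.0) -> pd.DataFrame:
        """Tidy frame with columns year, revenue, expenditure, balance,
        in yuan divided by ``unit``."""
        return pd.DataFrame({
            "year": self.years.astype(int),
            "revenue": self.revenue / unit,
            "expenditure": self.expenditure / unit,
            "balance": self.balance / unit,
        })

    def summary(self, unit: float = 1e9) -> str:
        """Human-readable digest (monetary values in ``unit`` yuan)."""
        u = unit
        s = self.scheme
        lines = [
            "LTCI fund trajectory",
            "=" * 56,
            f"scheme: payment rate {s.individual_payment_rate:.2%}, "
            f"severe disability rate {s.severe_disability_rate:.2%}, "
            f"reimbursement {s.reimbursement_ratio:.0%}",
            f"horizon: {self.years[0]}-{self.years[-1]}  (unit: {u:g} yuan)",
            f"first-year revenue      {self.revenue[0] / u:14.3f}",
            f"first-year expenditure  {self.expenditure[0] / u:14.3f}",
            f"peak balance            {self.peak_value / u:14.3f}  in {self.peak_year}",
            f"terminal balance        {self.terminal_balance / u:14.3f}  in {self.years[-1]}",
        ]
        d = self.first_deficit_year
        lines.append(f"first deficit year      {d if d is not None else '-':>14}")
        return "\n".join(lines)

    def plot(self, ax=None, unit: float = 1e9, label: str | None = None):
        from .plotting import plot_balance
        return plot_balance([self], ax=ax, unit=unit,
                            labels=[label] if label else None)


# ---------------------------------------------------------------------------
# the model object


class LTCIFundModel:
    """System-dynamics model of the LTCI fund for one parameter world.

    Parameters
    ----------
    params
        The model world (base-year states, growth rates, schedule).
    employees_override
        Optional year -> insured-employees mapping/callable replacing the
        exponential employee path, e.g. from a fitted urban-employee link.
    """

    def __init__(self, params: ParameterSet,
                 employees_override: Mapping[int, float] | Callable[[int], float] | None = None):
        self.params = params
        self.employees_override = employees_override
        self._horizon_states: tuple[list[PopulationState], list[EconomicState]] | None = None

    @classmethod
    def from_config(cls, path) -> "LTCIFundModel":
        from .io import load_config
        params, _ = load_config(path)
        return cls(params)

    # -- projections -------------------------------------------------------

    def project_population(self, years: Sequence[int] | None = None) -> list[PopulationState]:
        return project_population(self.params, years, self.employees_override)

    def project_economy(self, years: Sequence[int] | None = None) -> list[EconomicState]:
        return project_economy(self.params, years)

    def backcast(self, years: Sequence[int]) -> pd.DataFrame:
        """Model paths of the historically observable quantities over
        ``years`` (used by the historical validation test)."""
        pops = self.project_population(years)
        econs = self.project_economy(years)
        return pd.DataFrame({
            "year": list(years),
            "insured_urban_employees": [p.insured_employees for p in pops],
            "insured_retirees": [p.insured_retirees for p in pops],
            "insured_residents": [p.insured_residents for p in pops],
            "resident_income": [e.resident_income_base for e in econs],
            "wage": [e.wage_base for e in econs],
        }).set_index("year")

    # -- simulation --------------------------------------------------------

    def simulate(self, scheme: Scheme) -> FundTrajectory:
        """Run the annual stock-flow simulation over the horizon.

        Deterministic; the trajectory satisfies
        balance(t) = balance(t-1) + revenue(t) - expenditure(t) with
        balance(t0 - 1) = initial_balance.
        """
        params = self.params
        years = list(params.horizon_years)
        if self._horizon_states is None:
            # projections depend only on params, not the scheme: cache them
            self._horizon_states = (self.project_population(years),
                                    self.project_economy(years))
        pops, econs = self._horizon_states
        revenue = np.empty(len(years))
        expenditure = np.empty(len(years))
        balance = np.empty(len(years))
        prev = params.initial_balance
        for i, (pop, econ) in enumerate(zip(pops, econs)):
            revenue[i] = annual_revenue(pop, econ, scheme, params.schedule)
            expenditure[i] = annual_expenditure(pop, econ, scheme, params.disability_base)
            prev = step_balance(prev, revenue[i], expenditure[i])
            balance[i] = prev
        return FundTrajectory(np.asarray(years), revenue, expenditure, balance,
                              scheme, params.initial_balance)

    def validate_history(self, observed, threshold: float = 10.0,
                         absolute: bool = False):
        """Back-test the model against observed historical series; see
        :func:`ltcifund.calibration.historical_test`."""
        from .calibration import historical_test
        return historical_test(self.params, observed, threshold=threshold,
                               absolute=absolute, model=self)


def run_simulation(params: ParameterSet, scheme: Scheme) -> FundTrajectory:
    """Functional wrapper around :meth:`LTCIFundModel.simulate`."""
    return LTCIFundModel(params).simulate(scheme)
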