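"""Scenario grid construction and sustainability screening.

A financing scheme is *appropriate* when, over the forecast horizon, its
cumulative balance (i) never dips below zero, (ii) is not excessive
(above the policy threshold, default 3 trillion yuan), (iii) peaks in
the late period of the forecast (default: the final five years), and
(iv) its reimbursement ratio lies in the recommended 80-90% band.
Screening enumerates every violated rule, not just the first.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import FundTrajectory, LTCIFundModel
from .params import ConfigError, ParameterSet, Scheme

__all__ = [
    "ScenarioGrid",
    "ScreeningRules",
    "ScreeningResult",
    "GridResults",
    "build_scenario_grid",
    "run_grid",
    "screen_trajectory",
    "select_appropriate",
    "DEFAULT_LEVELS",
]

#: The standard factorial levels: 3 payment rates x 3 severe disability
#: rates x 5 reimbursement ratios = 45 schemes.
DEFAULT_LEVELS = {
    "payment_rate_levels": (0.0008, 0.0009, 0.0010),
    "disability_rate_levels": (0.0025, 0.0030, 0.0035),
    "reimbursement_levels": (0.70, 0.75, 0.80, 0.85, 0.90),
}

_TOL = 1e-9  # float guard on band/threshold comparisons


@dataclass(frozen=True)
class ScenarioGrid:
    payment_rate_levels: tuple[float, ...]
    disability_rate_levels: tuple[float, ...]
    reimbursement_levels: tuple[float, ...]
    schemes: tuple[Scheme, ...]

    def __len__(self) -> int:
        return len(self.schemes)

    def __iter__(self):
        return iter(self.schemes)


def build_scenario_grid(payment_rate_levels: Sequence[float] | None = None,
                        disability_rate_levels: Sequence[float] | None = None,
                        reimbursement_levels: Sequence[float] | None = None,
                        ) -> ScenarioGrid:
    """Full cross product of the three level lists, payment rate varying
    outermost and reimbursement innermost.  Defaults are the published
    levels (45 schemes)."""
    levels = {
        "payment_rate_levels": payment_rate_levels,
        "disability_rate_levels": disability_rate_levels,
        "reimbursement_levels": reimbursement_levels,
    }
    for name, default in DEFAULT_LEVELS.items():
        vals = levels[name]
        vals = tuple(default if vals is None else vals)
        if not vals:
            raise ConfigError(f"{name}: must be non-empty")
        if len(set(vals)) != len(vals):
            raise ConfigError(f"{name}: duplicate levels {vals}")
        if not all(0.0 < v < 1.0 or (name == "reimbursement_levels" and v == 1.0)
                   for v in vals):
            raise ConfigError(f"{name}: levels must lie in (0, 1), got {vals}")
        levels[name] = vals
    schemes = tuple(
        Scheme(r, s, m)
        for r, s, m in itertools.product(levels["payment_rate_levels"],
                                         levels["disability_rate_levels"],
                                         levels["reimbursement_levels"]))
    return ScenarioGrid(levels["payment_rate_levels"],
                        levels["disability_rate_levels"],
                        levels["reimbursement_levels"], schemes)


@dataclass(frozen=True)
class ScreeningRules:
    """Sustainability rules applied to a balance trajectory.

    excess_scope is 'terminal' (default) or 'any': whether the excess
    threshold is tested on the final balance only or on every year.
    ``require_interior_peak`` additionally rejects trajectories whose
    maximum sits on the final year (a strictly increasing curve with no
    inflection inside the horizon).
    """

    excess_threshold: float = 3e12
    excess_scope: str = "terminal"
    late_peak_window: int = 5
    reimbursement_band: tuple[float, float] = (0.80, 0.90)
    require_interior_peak: bool = False

    def __post_init__(self) -> None:
        if self.excess_threshold <= 0:
            raise ConfigError("excess_threshold: must be > 0")
        if self.excess_scope not in ("terminal", "any"):
            raise ConfigError("excess_scope: must be 'terminal' or 'any'")
        if self.late_peak_window < 1:
            raise ConfigError("late_peak_window: must be >= 1")
        lo, hi = self.reimbursement_band
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"reimbursement_band: invalid band {self.reimbursement_band}")


@dataclass(frozen=True)
class ScreeningResult:
    """Rule flags and verdict for one scheme's trajectory."""

    scheme: Scheme
    has_deficit: bool
    first_deficit_year: int | None
    is_excessive: bool
    peak_year: int
    peak_value: float
    terminal_balance: float
    late_peak: bool
    in_reimbursement_band: bool
    reasons: tuple[str, ...]
    trajectory: FundTrajectory | None = field(default=None, repr=False, compare=False)

    @property
    def verdict(self) -> str:
        return "appropriate" if not self.reasons else "rejected"

    @property
    def appropriate(self) -> bool:
        return not self.reasons

    def to_dict(self) -> dict:
        s = self.scheme
        return {
            "scheme": {
                "individual_payment_rate": s.individual_payment_rate,
                "severe_disability_rate": s.severe_disability_rate,
                "reimbursement_ratio": s.reimbursement_ratio,
            },
            "has_deficit": self.has_deficit,
            "first_deficit_year": self.first_deficit_year,
            "is_excessive": self.is_excessive,
            "peak_year": self.peak_year,
            "peak_value": self.peak_value,
            "terminal_balance": self.terminal_balance,
            "late_peak": self.late_peak,
            "in_reimbursement_band": self.in_reimbursement_band,
            "verdict": self.verdict,
            "reasons": list(self.reasons),
        }


def screen_trajectory(traj: FundTrajectory,
                      rules: ScreeningRules | None = None) -> ScreeningResult:
    """Apply the sustainability rules to one trajectory.

    Pure function of (trajectory, rules); the peak year breaks ties on
    the latest year attaining the maximum.
    """
    rules = rules if rules is not None else ScreeningRules()
    bal = traj.balance
    has_deficit = bool(np.any(bal < 0.0))
    if rules.excess_scope == "terminal":
        is_excessive = bool(traj.terminal_balance > rules.excess_threshold * (1 + _TOL))
    else:
        is_excessive = bool(np.any(bal > rules.excess_threshold * (1 + _TOL)))
    peak_year = traj.peak_year
    late_start = int(traj.years[-1]) - rules.late_peak_window + 1
    late_peak = peak_year >= late_start
    if rules.require_interior_peak and peak_year == int(traj.years[-1]):
        late_peak = False
    lo, hi = rules.reimbursement_band
    in_band = (lo - _TOL) <= traj.scheme.reimbursement_ratio <= (hi + _TOL)

    reasons = []
    if has_deficit:
        reasons.append("deficit")
    if is_excessive:
        reasons.append("excessive_balance")
    if not late_peak:
        reasons.append("early_peak")
    if not in_band:
        reasons.append("reimbursement_out_of_band")
    return ScreeningResult(traj.scheme, has_deficit, traj.first_deficit_year,
                           is_excessive, peak_year, traj.peak_value,
                           traj.terminal_balance, late_peak, in_band,
                           tuple(reasons), traj)


def select_appropriate(results: Iterable[ScreeningResult],
                       rules: ScreeningRules | None = None) -> list[ScreeningResult]:
    """Filter to appropriate schemes, preserving grid order; idempotent.

    When ``rules`` is given the trajectories are re-screened under them
    first, so relaxed rules can only grow the selection.
    """
    results = list(results)
    if rules is not None:
        results = [screen_trajectory(r.trajectory, rules) if r.trajectory is not None else r
                   for r in results]
    return [r for r in results if r.appropriate]


class GridResults:
    """Screening results for every scheme of one grid run, in grid order."""

    def __init__(self, grid: ScenarioGrid, results: Sequence[ScreeningResult],
                 rules: ScreeningRules):
        self.grid = grid
        self.results = list(results)
        self.rules = rules

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def appropriate(self) -> list[ScreeningResult]:
        return select_appropriate(self.results)

    def to_frame(self, unit: float = 1e9) -> pd.DataFrame:
        """One row per scheme with flags and balances in ``unit`` yuan."""
        rows = []
        for r in self.results:
            s = r.scheme
            rows.append({
                "payment_rate_pct": s.individual_payment_rate * 100,
                "disability_rate_pct": s.severe_disability_rate * 100,
                "reimbursement_pct": s.reimbursement_ratio * 100,
                "peak_year": r.peak_year,
                "peak_balance": r.peak_value / unit,
                "terminal_balance": r.terminal_balance / unit,
                "has_deficit": r.has_deficit,
                "is_excessive": r.is_excessive,
                "late_peak": r.late_peak,
                "in_band": r.in_reimbursement_band,
                "verdict": r.verdict,
                "reasons": ";".join(r.reasons),
            })
        return pd.DataFrame(rows)

    def selection_table(self, unit: float = 1e9) -> pd.DataFrame:
        """Table of appropriate schemes in the published layout:
        rates in percent, peak value/year and terminal balance in
        ``unit`` yuan."""
        rows = []
        for i, r in enumerate(self.appropriate(), start=1):
            s = r.scheme
            rows.append({
                "scheme": i,
                "payment_rate_pct": s.individual_payment_rate * 100,
                "disability_rate_pct": s.severe_disability_rate * 100,
                "reimbursement_pct": s.reimbursement_ratio * 100,
                "peak_balance": r.peak_value / unit,
                "peak_year": r.peak_year,
                "terminal_balance": r.terminal_balance / unit,
            })
        return pd.DataFrame(rows)

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            "rules": {
                "excess_threshold": self.rules.excess_threshold,
                "excess_scope": self.rules.excess_scope,
                "late_peak_window": self.rules.late_peak_window,
                "reimbursement_band": list(self.rules.reimbursement_band),
                "require_interior_peak": self.rules.require_interior_peak,
            },
            "n_schemes": len(self.results),
            "n_appropriate": len(self.appropriate()),
            "results": [r.to_dict() for r in self.results],
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self, unit: float = 1e9) -> str:
        sel = self.appropriate()
        lines = [
            "Scenario grid screening",
            "=" * 56,
            f"schemes simulated: {len(self.results)}   appropriate: {len(sel)}",
            f"rules: deficit-free, "
            f"{'terminal' if self.rules.excess_scope == 'terminal' else 'any-year'} "
            f"balance <= {self.rules.excess_threshold:g} yuan, "
            f"peak in final {self.rules.late_peak_window} years, "
            f"reimbursement in [{self.rules.reimbursement_band[0]:.0%}, "
            f"{self.rules.reimbursement_band[1]:.0%}]",
            "",
        ]
        if sel:
            lines.append(self.selection_table(unit).to_string(index=False))
        return "\n".join(lines)


def run_grid(params: ParameterSet, grid: ScenarioGrid | None = None,
             rules: ScreeningRules | None = None) -> GridResults:
    """Simulate and screen every scheme in the grid.

    Deterministic: results order matches grid order and re-running is
    bit-identical.  Simulation errors are re-raised with the offending
    scheme identified.
    """
    grid = grid if grid is not None else build_scenario_grid()
    rules = rules if rules is not None else ScreeningRules()
    model = LTCIFundModel(params)
    results = []
    for scheme in grid:
        try:
            traj = model.simulate(scheme)
        except Exception as exc:
            raise type(exc)(f"scheme {scheme.label()}: {exc}") from exc
        results.append(screen_trajectory(traj, rules))
    return GridResults(grid, results, rules)
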