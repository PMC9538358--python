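"""Calibration and historical validation.

Two jobs live here: the ordinary-least-squares link between the insured
employee population and the total urban-employee population (used to
drive the employee path from an external employment projection), and
the historical back-test — simulate the observable quantities over a
past window, compare with observed data, and gate on the mean relative
error being under a threshold (default 10%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import ConfigError, ParameterSet

__all__ = [
    "LinkModel",
    "HistoricalSeries",
    "ValidationReport",
    "fit_linear_link",
    "fit_growth_rate",
    "mean_relative_error",
    "historical_test",
    "KNOWN_SERIES",
]

#: Series labels the model can back-cast, mapped in LTCIFundModel.backcast.
KNOWN_SERIES = ("insured_urban_employees", "insured_retirees",
                "insured_residents", "resident_income", "wage")

#: Series the historical test requires by default: insured urban
#: employees (demographic factor) and per-capita disposable income of
#: urban residents (economic factor).
DEFAULT_REQUIRED = ("insured_urban_employees", "resident_income")


@dataclass(frozen=True)
class LinkModel:
    """OLS line y = slope * x + intercept linking two population series."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigError("n_points: need at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ConfigError(f"r_squared: must lie in [0, 1], got {self.r_squared}")

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_linear_link(x: Sequence[float], y: Sequence[float]) -> LinkModel:
    """Ordinary least squares fit of y on x.

    Raises a degenerate-design error when x is constant.  A constant y
    yields slope 0 and r-squared 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x, y: must be equal-length 1-d series")
    if len(x) < 2:
        raise ConfigError("x: need at least 2 points")
    if np.ptp(x) == 0.0:
        raise ConfigError("x: constant series, regression design is degenerate")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return LinkModel(float(res.slope), float(res.intercept), r2, len(x))


def fit_growth_rate(years: Sequence[int], values: Sequence[float]) -> float:
    """Recover a constant annual growth fraction from an exponential
    series by log-linear OLS: slope of log(value) on year, returned as
    exp(slope) - 1."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ConfigError("values: must be positive for log-linear growth fitting")
    res = stats.linregress(np.asarray(years, dtype=float), np.log(values))
    return float(np.expm1(res.slope))


@dataclass(frozen=True)
class HistoricalSeries:
    """Aligned observed and simulated year-indexed values for one quantity."""

    years: np.ndarray
    observed: np.ndarray
    simulated: np.ndarray
    label: str

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.observed) == len(self.simulated) == n):
            raise ConfigError(f"{self.label}: series lengths differ")
        if n < 2:
            raise ConfigError(f"{self.label}: need at least 2 years")
        if np.any(np.asarray(self.observed) <= 0):
            raise ConfigError(f"{self.label}: observed values must be > 0 "
                              "(relative error undefined otherwise)")


def mean_relative_error(series: HistoricalSeries, absolute: bool = False) -> float:
    """Mean relative error of simulated vs observed, in percent.

    Signed by default: mean of (simulated - observed) / observed * 100,
    so systematic under-prediction is negative.  ``absolute=True``
    averages |relative error| instead.
    """
    rel = (np.asarray(series.simulated, dtype=float)
           - np.asarray(series.observed, dtype=float)) / np.asarray(series.observed, dtype=float)
    if absolute:
        rel = np.abs(rel)
    return float(np.mean(rel) * 100.0)


@dataclass(frozen=True)
class ValidationReport:
    """Per-series mean relative errors with the pass/fail gate."""

    errors: dict[str, float]
    threshold: float = 10.0
    series: tuple[HistoricalSeries, ...] = field(default=(), repr=False)

    @property
    def pass_flag(self) -> bool:
        return all(abs(e) < self.threshold for e in self.errors.values())

    def to_dict(self) -> dict:
        return {
            "threshold_percent": self.threshold,
            "mean_relative_error_percent": dict(self.errors),
            "pass": self.pass_flag,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        lines = ["Historical validation", "=" * 42]
        for label, err in self.errors.items():
            lines.append(f"{label:28s} {err:+8.3f}%")
        lines.append(f"threshold: |error| < {self.threshold:g}%  ->  "
                     f"{'PASS' if self.pass_flag else 'FAIL'}")
        return "\n".join(lines)


def _as_series_map(observed) -> dict[str, pd.Series]:
    """Accept {label: Series-indexed-by-year} or a tidy frame with
    columns year, value, series_label."""
    if isinstance(observed, pd.DataFrame):
        out = {}
        for label, grp in observed.groupby("series_label"):
            out[str(label)] = pd.Series(grp["value"].to_numpy(),
                                        index=grp["year"].to_numpy(dtype=int))
        return out
    return {str(k): pd.Series(v) for k, v in dict(observed).items()}


def historical_test(params: ParameterSet, observed,
                    threshold: float = 10.0, absolute: bool = False,
                    required: Sequence[str] = DEFAULT_REQUIRED,
                    model=None) -> ValidationReport:
    """Back-cast the model over the observed window and gate on mean
    relative error.

    ``observed`` maps series labels to year-indexed values (or is a
    tidy frame with columns year, value, series_label).  Every required
    series must be present; every provided series must be one the model
    can simulate (see ``KNOWN_SERIES``).  Passes iff all |mean errors|
    are under ``threshold`` percent.
    """
    from .model import LTCIFundModel

    series_map = _as_series_map(observed)
    for name in required:
        if name not in series_map:
            raise ConfigError(f"observed: missing required series {name!r}")
    unknown = set(series_map) - set(KNOWN_SERIES)
    if unknown:
        raise ConfigError(f"observed: cannot simulate series {sorted(unknown)!r}; "
                          f"known series are {list(KNOWN_SERIES)}")

    mdl = model if model is not None else LTCIFundModel(params)
    errors: dict[str, float] = {}
    built: list[HistoricalSeries] = []
    for label, obs in series_map.items():
        years = np.asarray(obs.index, dtype=int)
        sim = mdl.backcast(years)[label].to_numpy()
        hs = HistoricalSeries(years, obs.to_numpy(dtype=float), sim, label)
        errors[label] = mean_relative_error(hs, absolute=absolute)
        built.append(hs)
    return ValidationReport(errors, threshold, tuple(built))
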