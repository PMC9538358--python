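"""A single figure helper: cumulative balance curves over the horizon."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt

from .model import FundTrajectory

__all__ = ["plot_balance"]


def plot_balance(trajectories: Iterable[FundTrajectory], ax=None, unit: float = 1e9,
                 labels: Sequence[str] | None = None, show_zero: bool = True):
    """Plot balance curves (in ``unit`` yuan) for one or more schemes."""
    trajectories = list(trajectories)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    for i, traj in enumerate(trajectories):
        label = labels[i] if labels else traj.scheme.label()
        ax.plot(traj.years, traj.balance / unit, label=label)
    if show_zero:
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("year")
    ax.set_ylabel(f"cumulative fund balance ({unit:g} yuan)")
    ax.legend(fontsize=8)
    return ax
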