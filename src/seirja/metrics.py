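"""Observables: polarizability, peaks, daily comment proportions, RMSE, RSD."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .heterogeneity import State

__all__ = [
    "CurveSeries",
    "polarizability",
    "peak_count",
    "comment_proportion_series",
    "rmse",
    "relative_standard_deviation",
]


@dataclass
class CurveSeries:
    """A labelled time series (steps or days on the time axis)."""

    t: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.t) != len(self.values):
            raise ValueError("time axis and values differ in length")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "CurveSeries":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), values=df["value"].to_numpy(), label=label)


def polarizability(attitudes, threshold: float = 0.8) -> float:
    """Fraction of (informed) agents with an extreme opinion, |x| > threshold.

    The caller passes only the attitudes of agents that actually hold one;
    an empty collection yields 0 by convention.
    """
    x = np.asarray(attitudes, dtype=float)
    if x.size == 0:
        return 0.0
    return float((np.abs(x) > threshold).sum() / x.size)


def peak_count(result: SimulationResult, compartment: State | int) -> int:
    """Maximum over time of a compartment's count."""
    return int(result.count_series(compartment).max())


def comment_proportion_series(
    result: SimulationResult, steps_per_day: int,
    n_days: int | None = None, first_day_only: bool = False,
) -> CurveSeries:
    """Daily distinct-commenter proportion of a run.

    An agent "comments" on a day if it is in the communication state at any
    step of that day; the denominator is the number of distinct agents ever
    communicating during the run.  By default an agent counts once per day
    it is active (so the series can sum above 1, the way daily-commenter
    counts on a platform behave); ``first_day_only`` attributes each agent
    to its first active day instead.
    """
    if steps_per_day < 1:
        raise ValueError("steps_per_day must be >= 1")
    sets = result.communicators
    total: set = set()
    for s in sets:
        total |= s
    days = (len(sets) + steps_per_day - 1) // steps_per_day
    if n_days is not None:
        days = max(days, n_days)
    values = np.zeros(days)
    seen: set = set()
    for d in range(days):
        day_agents: set = set()
        for s in sets[d * steps_per_day:(d + 1) * steps_per_day]:
            day_agents |= s
        if first_day_only:
            day_agents -= seen
            seen |= day_agents
        values[d] = len(day_agents) / len(total) if total else 0.0
    if n_days is not None:
        values = values[:n_days]
        days = n_days
    return CurveSeries(t=np.arange(days), values=values, label=result.termination)


def rmse(curve_a: CurveSeries, curve_b: CurveSeries) -> float:
    """Root-mean-square difference of two equal-length curves."""
    if len(curve_a) != len(curve_b):
        raise ValueError(f"length mismatch: {len(curve_a)} vs {len(curve_b)}")
    return float(np.sqrt(np.mean((curve_a.values - curve_b.values) ** 2)))


def relative_standard_deviation(values) -> float:
    """100 * sample SD / mean; 0 for a single value or zero mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if v.size == 1:
        return 0.0
    mean = v.mean()
    if mean == 0:
        return 0.0
    return float(100.0 * v.std(ddof=1) / mean)
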