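"""Synthetic comment-stream generator.

Real platform comment data (per-comment user id, hourly timestamp and
sentiment score in [-1, 1]) is not redistributable, so validation runs
against a synthetic stream with the same shape and summary statistics:
per-period comment count, distinct-user count, duration in days, the share
and mean sentiment of the first three hours.

The stream is not sampled from arbitrary noise: a coupled
dissemination/polarization simulation at fixture scale produces the raw
events (each communicating agent emits a comment per step, sentiment =
attitude + small Gaussian noise), and the events are then resampled to the
requested totals.  This keeps the stream's temporal and sentiment
structure model-plausible — an early burst, gradual spread, heavy-tailed
user activity and growing extremity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import initialize, step
from .heterogeneity import ModelParams, State
from .metrics import CurveSeries

__all__ = ["FixtureSpec", "CommentStream", "generate_fixture"]


@dataclass
class FixtureSpec:
    """Targets the generated stream must hit.

    ``extremity_level`` in [0, 1] scales the mainstream step of the
    underlying simulation (0 freezes conformity, hence sentiments stay near
    the initial mean up to the emission noise).
    """

    n_comments: int = 3665
    n_users: int = 1961
    duration_days: int = 9
    first3h_mean_sentiment: float = -0.11
    first3h_share: float = 0.05
    extremity_level: float = 0.5
    start: str = "2020-08-18"

    def __post_init__(self) -> None:
        if self.n_users > self.n_comments:
            raise ValueError("n_users cannot exceed n_comments")
        if self.duration_days < 1:
            raise ValueError("duration must be at least 1 day")
        if not 0 < self.first3h_share <= 1:
            raise ValueError("first3h_share must be in (0, 1]")
        if not 0 <= self.extremity_level <= 1:
            raise ValueError("extremity_level must be in [0, 1]")


@dataclass
class CommentStream:
    """Timestamped sentiment records plus period metadata."""

    records: pd.DataFrame          # columns: user_id, timestamp, sentiment
    start: pd.Timestamp
    duration_days: int

    @property
    def n_comments(self) -> int:
        return len(self.records)

    @property
    def n_users(self) -> int:
        return int(self.records["user_id"].nunique())

    def _first3h_mask(self) -> pd.Series:
        return self.records["timestamp"] < self.start + pd.Timedelta(hours=3)

    @property
    def first3h_share(self) -> float:
        return float(self._first3h_mask().mean())

    @property
    def first3h_mean_sentiment(self) -> float:
        return float(self.records.loc[self._first3h_mask(), "sentiment"].mean())

    def daily_proportions(self) -> CurveSeries:
        """Distinct commenting users per day over distinct users overall."""
        day = ((self.records["timestamp"] - self.start).dt.total_seconds()
               // 86400).astype(int)
        per_day = self.records.groupby(day)["user_id"].nunique()
        values = np.zeros(self.duration_days)
        for d, c in per_day.items():
            if 0 <= d < self.duration_days:
                values[d] = c / self.n_users
        return CurveSeries(t=np.arange(self.duration_days), values=values,
                           label="actual comment proportion")

    def daily_polarizability(self, threshold: float = 0.8) -> CurveSeries:
        """Share of extreme comments (|score| > threshold) per day."""
        day = ((self.records["timestamp"] - self.start).dt.total_seconds()
               // 86400).astype(int)
        values = np.zeros(self.duration_days)
        grouped = self.records.groupby(day)["sentiment"]
        for d, s in grouped:
            if 0 <= d < self.duration_days:
                values[d] = float((s.abs() > threshold).mean())
        return CurveSeries(t=np.arange(self.duration_days), values=values,
                           label="actual polarizability")

    def to_csv(self, path: str | Path) -> None:
        df = self.records.copy()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, duration_days: int | None = None) -> "CommentStream":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        start = df["timestamp"].min().normalize()
        if duration_days is None:
            duration_days = int((df["timestamp"].max() - start).days) + 1
        return cls(records=df, start=start, duration_days=duration_days)


def _simulate_events(spec: FixtureSpec, steps_per_day: int, rng: np.random.Generator):
    """Raw (day, sentiment) comment events from a fixture-scale simulation."""
    horizon = spec.duration_days * steps_per_day
    params = ModelParams(
        N=200,
        attitude_mean=spec.first3h_mean_sentiment,
        attitude_sd=0.4 ** 0.5,  # N(mean, variance) convention
        gamma=0.2 * spec.extremity_level,
        z0=max(1, round(0.75 * horizon)),
        init_comm_frac=min(0.5, max(0.02, spec.first3h_share)),
        max_steps=horizon,
    )
    st = initialize(params, seed=int(rng.integers(0, 2**31 - 1)))
    days, sentiments = [], []
    for t in range(horizon):
        step(st, params)
        commenting = np.flatnonzero(st.state == int(State.COMMUNICATION))
        if len(commenting):
            noise = rng.normal(0.0, 0.1, size=len(commenting))
            s = np.clip(st.x[commenting] + noise, -1.0, 1.0)
            days.extend([t // steps_per_day] * len(commenting))
            sentiments.extend(s.tolist())
    return np.asarray(days), np.asarray(sentiments)


def generate_fixture(spec: FixtureSpec, seed: int | None = None,
                     steps_per_day: int = 5) -> CommentStream:
    """Generate a stream hitting the spec's totals.

    Comment and user counts and the first-3-hours share are exact by
    construction; the first-3-hours mean sentiment is matched by
    re-centering (within clipping) and lands within about +/-0.02.
    """
    rng = np.random.default_rng(seed)
    days, sentiments = _simulate_events(spec, steps_per_day, rng)
    if len(days) == 0:  # degenerate simulation; fall back to the prior
        days = rng.integers(0, spec.duration_days, size=1000)
        sentiments = np.clip(
            rng.normal(spec.first3h_mean_sentiment, 0.4, size=1000), -1, 1)

    n_first = max(1, round(spec.first3h_share * spec.n_comments))
    n_rest = spec.n_comments - n_first

    # daily quotas proportional to the simulated activity profile
    day_counts = np.bincount(days, minlength=spec.duration_days).astype(float)
    if day_counts.sum() == 0:
        day_counts[:] = 1.0
    day_counts = np.maximum(day_counts, 1e-9)
    quotas = np.floor(n_rest * day_counts / day_counts.sum()).astype(int)
    for k in range(n_rest - quotas.sum()):  # distribute the remainder
        quotas[k % spec.duration_days] += 1

    rows_day, rows_hour, rows_sent = [], [], []

    day0 = sentiments[days == 0]
    pool0 = day0 if len(day0) else sentiments
    first = rng.choice(pool0, size=n_first, replace=True)
    first = first + (spec.first3h_mean_sentiment - first.mean())
    first = np.clip(first, -1.0, 1.0)
    if abs(first.mean() - spec.first3h_mean_sentiment) > 1e-6:
        first = np.clip(first + (spec.first3h_mean_sentiment - first.mean()), -1, 1)
    rows_day.extend([0] * n_first)
    rows_hour.extend(rng.integers(0, 3, size=n_first).tolist())
    rows_sent.extend(first.tolist())

    for d in range(spec.duration_days):
        q = int(quotas[d])
        if q == 0:
            continue
        pool = sentiments[days == d]
        if len(pool) == 0:
            pool = sentiments
        s = rng.choice(pool, size=q, replace=True)
        lo = 3 if d == 0 else 0
        rows_day.extend([d] * q)
        rows_hour.extend(rng.integers(lo, 24, size=q).tolist())
        rows_sent.extend(s.tolist())

    # exactly n_users distinct users: one guaranteed appearance each, the
    # remaining comments drawn uniformly from the user pool
    n = len(rows_day)
    users = np.concatenate([
        np.arange(spec.n_users),
        rng.integers(0, spec.n_users, size=n - spec.n_users),
    ])
    rng.shuffle(users)

    start = pd.Timestamp(spec.start)
    ts = [start + pd.Timedelta(days=int(d), hours=int(h))
          for d, h in zip(rows_day, rows_hour)]
    df = pd.DataFrame({"user_id": users, "timestamp": ts, "sentiment": rows_sent})
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return CommentStream(records=df, start=start, duration_days=spec.duration_days)
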