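"""Turning forum post logs into per-topic author time series.

A topic's activity series is the number of distinct authors (thread
starters and commenters alike) posting on the topic per calendar period,
usually a month.  Series are optionally smoothed with a trailing moving
average, and classified as *spikey* (activity exceeds mean + 2 sd at some
period — an event-driven burst worth fitting with the diffusion model) or
*chatter* (ongoing discussion without epidemic spikes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ObservedSeries",
    "SpikeReport",
    "SpikeDetector",
    "count_distinct_authors",
    "moving_average",
    "detect_spikes",
    "classify_topic",
]

POST_COLUMNS = ["thread_id", "post_id", "author_id", "timestamp", "topic_label"]

_PERIOD_FREQ = {"month": "M", "day": "D"}


class EmptySeriesError(ValueError):
    """No posts matched the requested topic."""


@dataclass
class ObservedSeries:
    """Per-period counts of active distinct authors for one topic.

    ``t`` is a consecutive integer period index starting at 0; ``counts``
    are non-negative reals (integers for raw counts, reals once smoothed).
    ``dates`` optionally carries the calendar label of each period.
    """

    topic_label: str
    t: np.ndarray
    counts: np.ndarray
    smoothed: bool = False
    dates: list[str] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.t) != len(self.counts):
            raise ValueError("t and counts must have equal length")
        if len(self.t) and not np.array_equal(self.t, np.arange(self.t[0], self.t[0] + len(self.t))):
            raise ValueError("t must be consecutive integers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.counts)

    def replace(self, **kw) -> "ObservedSeries":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SpikeReport:
    """Result of the mean + 2 sd burst rule on one series."""

    threshold: float
    spike_periods: list[int]
    is_spikey: bool
    series_mean: float
    series_sd: float


def count_distinct_authors(
    log: pd.DataFrame, topic: str, period: str = "month"
) -> ObservedSeries:
    """Count unique authors posting on ``topic`` per calendar period.

    ``log`` holds one row per post with columns thread_id, post_id,
    author_id, timestamp, topic_label.  Every period between the first and
    last matching post is represented; periods without posts count 0.
    Timestamps are bucketed in UTC.

    Raises
    ------
    EmptySeriesError
        If no post carries the topic label.
    ValueError
        If a matching post has an unparseable timestamp (the post_id is
        named) or ``period`` is not "month"/"day".
    """
    if period not in _PERIOD_FREQ:
        raise ValueError(f"period must be 'month' or 'day', got {period!r}")
    missing = [c for c in POST_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"post log lacks columns {missing}")

    matching = log[log["topic_label"] == topic]
    if matching.empty:
        raise EmptySeriesError(f"no posts carry topic label {topic!r}")

    ts = pd.to_datetime(matching["timestamp"], errors="coerce", utc=True)
    if ts.isna().any():
        bad = matching.loc[ts.isna(), "post_id"].iloc[0]
        raise ValueError(f"unparseable timestamp on post_id {bad!r}")

    freq = _PERIOD_FREQ[period]
    buckets = ts.dt.tz_localize(None).dt.to_period(freq)
    per_period = matching.groupby(buckets)["author_id"].nunique()
    full = pd.period_range(per_period.index.min(), per_period.index.max(), freq=freq)
    per_period = per_period.reindex(full, fill_value=0)

    return ObservedSeries(
        topic_label=topic,
        t=np.arange(len(per_period)),
        counts=per_period.to_numpy(dtype=float),
        dates=[str(p) for p in per_period.index],
    )


def moving_average(series: ObservedSeries, window: int) -> ObservedSeries:
    """Trailing moving average over the last ``window`` periods.

    The first window-1 periods average over all available history
    (edge-truncated), so the output keeps the input's length and the
    smoothing stays causal — usable for adaptive early-warning monitoring.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > series.n:
        raise ValueError(
            f"window ({window}) exceeds series length ({series.n})"
        )
    smoothed = (
        pd.Series(series.counts).rolling(window, min_periods=1).mean().to_numpy()
    )
    return series.replace(counts=smoothed, smoothed=True)


class SpikeDetector(BaseEstimator):
    """Flags periods whose count strictly exceeds mean + ``n_sd`` * sd.

    The standard deviation uses the population (divide-by-n) convention
    and the comparison is strict, so a constant series — sd 0, threshold
    equal to every value — reports no spikes.

    Attributes (after ``fit``)
    --------------------------
    threshold_ : float
    spike_periods_ : list of period indices above the threshold
    is_spikey_ : bool
    mean_, sd_ : series moments
    """

    def __init__(self, n_sd: float = 2.0):
        self.n_sd = n_sd

    def fit(self, X, y=None) -> "SpikeDetector":
        counts = X.counts if isinstance(X, ObservedSeries) else np.asarray(X, dtype=float).ravel()
        if len(counts) < 2:
            raise ValueError(
                "spike detection needs at least 2 periods (sd undefined)"
            )
        self.mean_ = float(np.mean(counts))
        self.sd_ = float(np.std(counts))  # population convention
        self.threshold_ = self.mean_ + self.n_sd * self.sd_
        self.spike_periods_ = [int(i) for i in np.flatnonzero(counts > self.threshold_)]
        self.is_spikey_ = bool(self.spike_periods_)
        return self

    def report(self) -> SpikeReport:
        return SpikeReport(
            threshold=self.threshold_,
            spike_periods=self.spike_periods_,
            is_spikey=self.is_spikey_,
            series_mean=self.mean_,
            series_sd=self.sd_,
        )


def detect_spikes(series: ObservedSeries) -> SpikeReport:
    """Apply the mean + 2 sd rule to a series."""
    return SpikeDetector().fit(series).report()


def classify_topic(series: ObservedSeries) -> str:
    """Label a (raw, unsmoothed) series "spikey" or "chatter".

    Chatter topics lack epidemic-style bursts and are normally excluded
    from diffusion fitting.
    """
    return "spikey" if detect_spikes(series).is_spikey else "chatter"
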