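"""Synthetic outbreaks and forum-style post logs with known ground truth.

The generator plays the observation process in reverse: a noiseless
trajectory comes from the deterministic model, monthly distinct-author
counts are read off I(t) (optionally perturbed by Gaussian or Poisson
observation noise), and a post log is fabricated so that counting distinct
authors per month recovers round(I(m)) exactly.  Everything is seeded, so
identical specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .model import InitialState, SIRParams, Trajectory, simulate
from .timeseries import POST_COLUMNS, ObservedSeries

__all__ = ["SyntheticSpec", "generate_series", "generate_post_log"]

#: Calendar month assigned to model time t = 0 in generated post logs.
LOG_EPOCH = "2004-04"


@dataclass
class SyntheticSpec:
    """Ground truth and observation model for one synthetic topic."""

    params: SIRParams
    init: InitialState
    horizon: int = 30
    noise_model: str = "none"
    noise_scale: float = 0.0
    seed: int = 0
    posts_per_author_per_month: float = 3.0
    topic_label: str = "synthetic-topic"
    author_carryover: float = 0.5

    def __post_init__(self) -> None:
        if self.horizon < 5:
            raise ValueError("horizon must be >= 5")
        if self.noise_model not in {"none", "gaussian", "poisson"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model == "none" and self.noise_scale > 0:
            warnings.warn(
                "noise_scale ignored with noise_model='none'", stacklevel=2
            )
        if self.posts_per_author_per_month <= 0:
            raise ValueError("posts_per_author_per_month must be positive")
        if not 0.0 <= self.author_carryover <= 1.0:
            raise ValueError("author_carryover must be in [0, 1]")


def generate_series(spec: SyntheticSpec) -> tuple[ObservedSeries, Trajectory]:
    """Simulate the trajectory and observe I(t) at integer months.

    Gaussian noise has sd = noise_scale * max I(t) and the observation is
    clipped at 0; Poisson noise draws counts with mean I(t).
    """
    traj = simulate(spec.params, spec.init, spec.horizon)
    rng = np.random.default_rng(spec.seed)
    counts = traj.I.copy()
    if spec.noise_model == "gaussian" and spec.noise_scale > 0:
        sd = spec.noise_scale * counts.max()
        counts = np.clip(counts + rng.normal(0.0, sd, size=len(counts)), 0.0, None)
    elif spec.noise_model == "poisson":
        counts = rng.poisson(counts).astype(float)
    series = ObservedSeries(
        topic_label=spec.topic_label, t=np.arange(len(counts)), counts=counts
    )
    return series, traj


def generate_post_log(trajectory: Trajectory, spec: SyntheticSpec) -> pd.DataFrame:
    """Fabricate a post log whose monthly distinct-author counts equal
    round(I(m)).

    For month m, round(I(m)) authors are active; a fraction of them carry
    over from the previous month (forum regulars), the rest are fresh ids
    — either way the number of distinct authors is fixed by construction.
    Each active author writes max(1, Poisson(posts_per_author_per_month))
    posts at timestamps uniform within the month; thread ids are assigned
    round-robin.
    """
    rng = np.random.default_rng(spec.seed + 1)
    active_counts = np.round(trajectory.I).astype(int)
    if not np.any(active_counts > 0):
        raise ValueError("trajectory rounds to zero authors in every month")

    months = pd.period_range(LOG_EPOCH, periods=len(active_counts), freq="M")
    rows: list[tuple] = []
    next_author = 0
    prev_authors: list[int] = []
    post_id = 0
    n_threads = 10
    for m, k in enumerate(active_counts):
        if k == 0:
            prev_authors = []
            continue
        n_carry = min(int(spec.author_carryover * k), len(prev_authors))
        carried = list(rng.choice(prev_authors, size=n_carry, replace=False))
        fresh = list(range(next_author, next_author + (k - n_carry)))
        next_author += k - n_carry
        authors = carried + fresh
        start = months[m].to_timestamp()
        month_seconds = (months[m] + 1).to_timestamp() - start
        for author in authors:
            n_posts = max(1, int(rng.poisson(spec.posts_per_author_per_month)))
            offsets = rng.random(n_posts) * month_seconds.total_seconds()
            for off in offsets:
                rows.append(
                    (
                        f"T{post_id % n_threads:03d}",
                        f"P{post_id:06d}",
                        f"A{author:05d}",
                        (start + pd.Timedelta(seconds=float(off))).isoformat(),
                        spec.topic_label,
                    )
                )
                post_id += 1
        prev_authors = authors
    return pd.DataFrame(rows, columns=POST_COLUMNS)
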