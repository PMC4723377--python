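"""Reading and writing the package's plain-text formats.

Series and trajectories travel as CSV, parameter sets and fit results as
JSON, configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import InitialState, SIRParams, Trajectory
from .timeseries import ObservedSeries

__all__ = [
    "read_series",
    "write_series",
    "read_params",
    "write_params",
    "write_trajectory",
    "read_trajectory",
    "load_yaml",
]


def write_series(series: ObservedSeries, path: str | Path) -> None:
    """Write a series as CSV with columns t, date, count."""
    dates = series.dates if series.dates is not None else [""] * series.n
    pd.DataFrame(
        {"t": series.t, "date": dates, "count": series.counts}
    ).to_csv(path, index=False)


def read_series(path: str | Path, topic_label: str | None = None) -> ObservedSeries:
    """Read a series CSV (columns t, count; date optional)."""
    df = pd.read_csv(path)
    if not {"t", "count"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t and count")
    dates = df["date"].astype(str).tolist() if "date" in df.columns else None
    return ObservedSeries(
        topic_label=topic_label or Path(path).stem,
        t=df["t"].to_numpy(),
        counts=df["count"].to_numpy(dtype=float),
        dates=dates,
    )


def write_params(
    params: SIRParams, init: InitialState, path: str | Path, **extra
) -> None:
    payload = {
        "alpha": params.alpha,
        "beta": params.beta,
        "mu": params.mu,
        "K": params.K,
        "S0": init.S0,
        "I0": init.I0,
        "R0": init.R0,
        **extra,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params(path: str | Path) -> tuple[SIRParams, InitialState]:
    d = json.loads(Path(path).read_text())
    params = SIRParams(alpha=d["alpha"], beta=d["beta"], mu=d["mu"], K=d["K"])
    init = InitialState(S0=d["S0"], I0=d.get("I0", 1.0), R0=d.get("R0", 0.0))
    return params, init


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"t": traj.t, "S": traj.S, "I": traj.I, "R": traj.R, "N": traj.N}
    ).to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t=df["t"].to_numpy(),
        S=df["S"].to_numpy(),
        I=df["I"].to_numpy(),
        R=df["R"].to_numpy(),
        N=df["N"].to_numpy() if "N" in df.columns else None,
    )


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, default=_to_jsonable) + "\n"
    )
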