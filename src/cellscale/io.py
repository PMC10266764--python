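"""Shared CSV/JSON readers and writers and run configuration.

CSV is the sole tabular format (the source data are simple tables): time
in hours under ``t_h``, measurements under ``value``, optional ``sigma``
and ``channel`` columns.  Structured results go to JSON with
deterministic key order, the package version, the seed and a hash of the
configuration so every run is reproducible from its report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "write_report", "config_hash"]

_REQUIRED = ("t_h", "value")


def read_timeseries(path: str | Path, channel: str | None = None) -> TimeSeries:
    """Read a channel time series from CSV, validate and sort by time.

    The header must contain ``t_h`` and ``value``; ``sigma`` and
    ``channel`` are optional.  Rows are sorted by time; duplicate times or
    non-finite values raise with the offending line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if channel is None:
        channel = str(df["channel"].iloc[0]) if "channel" in df.columns else "volume"
    if "channel" in df.columns:
        df = df[df["channel"] == channel]
        if df.empty:
            raise ValueError(f"{path}: no rows for channel {channel!r}")
    bad = df.index[~np.isfinite(df["t_h"]) | ~np.isfinite(df["value"])].tolist()
    if bad:
        lines = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at line(s) {lines}")
    df = df.sort_values("t_h")
    if df["t_h"].duplicated().any():
        raise ValueError(f"{path}: duplicate time points")
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return TimeSeries(
        t=df["t_h"].to_numpy(), y=df["value"].to_numpy(), sigma=sigma, label=channel
    )


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write a time series to the CSV schema the readers accept."""
    df = pd.DataFrame({"t_h": ts.t, "value": ts.y})
    if ts.sigma is not None:
        df["sigma"] = ts.sigma
    df["channel"] = ts.label
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(
    results: dict, path: str | Path, config: dict | None = None, seed: int | None = None
) -> dict:
    """Write a deterministic JSON report of a run.

    The report embeds the package version, the seed, the configuration and
    its hash; identical inputs produce byte-identical files.
    """
    from . import __version__

    report = {
        "package": "cellscale",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config or {}),
        "config_hash": config_hash(_jsonable(config or {})),
        "results": _jsonable(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
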