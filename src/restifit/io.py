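"""Readers and writers for the pipeline's CSV/JSON artifacts.

The interchange format for raw data is a tidy long CSV with columns
``organoid_id, treatment, channel, time_min, value`` (UTF-8, header
required, times in minutes).  Feature tables, percent-change matrices,
edge lists and reports are plain CSV; every run emits a JSON manifest
carrying the seed and configuration needed to regenerate it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import CHANNELS, Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "SchemaError",
    "read_trajectories",
    "write_trajectories",
    "frame_to_trajectories",
    "trajectories_to_frame",
    "read_feature_table",
    "write_feature_table",
    "write_manifest",
]

TRAJECTORY_COLUMNS = ("organoid_id", "treatment", "channel", "time_min", "value")

#: Units of each parameter as conventionally reported.
PARAM_UNITS = {
    "act_depoly1": "min^-1",
    "act_depoly2": "min^-1",
    "act_poly": "min^-1",
    "act_max": "RLU",
    "act_min": "RLU",
    "act_ss": "RLU",
    "dcd_max": "um",
    "k_repair": "um^2 min^-1",
    "k_run": "um min^-1",
    "k_stay": "um min^-1",
    "t_detach": "min",
    "t_max": "min",
    "t_min": "min",
}


class SchemaError(ValueError):
    """Input file violates the tidy trajectory schema."""


def frame_to_trajectories(frame: pd.DataFrame) -> list[Trajectory]:
    """Group a tidy trajectory table into per-organoid-channel series.

    Rows are sorted by time within each group; schema violations
    (missing columns, unknown channels, non-numeric fields) raise
    `SchemaError` with the offending rows identified.
    """
    missing = set(TRAJECTORY_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    bad = ~frame["channel"].isin(CHANNELS)
    if bad.any():
        rows = list(frame.index[bad][:5])
        raise SchemaError(
            f"unknown channel labels {sorted(set(frame.loc[bad, 'channel']))} "
            f"at rows {rows}"
        )
    for col in ("time_min", "value"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            rows = list(frame.index[vals.isna()][:5])
            raise SchemaError(f"non-numeric {col} at rows {rows}")
    out = []
    for (oid, channel), group in frame.groupby(["organoid_id", "channel"], sort=True):
        group = group.sort_values("time_min")
        treatments = group["treatment"].unique()
        if len(treatments) != 1:
            raise SchemaError(f"organoid {oid!r} has multiple treatment labels")
        out.append(
            Trajectory(
                organoid_id=str(oid),
                treatment=str(treatments[0]),
                channel=str(channel),
                times=group["time_min"].to_numpy(dtype=float),
                values=group["value"].to_numpy(dtype=float),
            )
        )
    return out


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "organoid_id": tr.organoid_id,
                "treatment": tr.treatment,
                "channel": tr.channel,
                "time_min": tr.times,
                "value": tr.values,
            }
        )
        for tr in trajectories
    ]
    return pd.concat(frames, ignore_index=True)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read the tidy trajectory CSV into grouped, time-sorted series."""
    return frame_to_trajectories(pd.read_csv(path))


def write_trajectories(data, path: str | Path) -> Path:
    """Write trajectories (list or tidy DataFrame) as CSV."""
    path = Path(path)
    frame = data if isinstance(data, pd.DataFrame) else trajectories_to_frame(data)
    frame.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    units = path.with_suffix(".units.json")
    units.write_text(json.dumps(PARAM_UNITS, indent=2, sort_keys=True))
    return path


def write_manifest(path: str | Path, seed: int, config: dict | str, **extra) -> Path:
    """Record run provenance (seed + configuration) as JSON."""
    path = Path(path)
    if isinstance(config, str):
        config = json.loads(config)
    manifest = {"seed": seed, "config": config, **extra}
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
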