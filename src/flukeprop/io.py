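"""Delimited-table and configuration I/O.

Tag series are CSV tables with columns ``time_s, gyro_y_rps, speed_mps,
depth_m``; lunge tables carry ``deployment_id, t_deceleration_s``; truth
sidecars one row per beat. Floats are written with ``%.10g`` so a
write/read round trip reproduces values to double precision for all
magnitudes that occur here. Configs are YAML key-value files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError, SchemaError
from .photogrammetry import WhaleMorphology
from .synthetic import SimConfig, SimTruth
from .tailbeats import LungeEvent, TagSeries

__all__ = [
    "read_tag_series",
    "write_tag_series",
    "read_lunges",
    "write_lunges",
    "write_truth",
    "read_truth",
    "read_morphology",
    "write_morphology",
    "read_sim_config",
    "write_sim_config",
    "read_deployment",
    "write_results",
]

TAG_COLUMNS = ["time_s", "gyro_y_rps", "speed_mps", "depth_m"]
FLOAT_FMT = "%.10g"


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_tag_series(path) -> TagSeries:
    """Read a tag table; validates schema and the time grid.

    Raises :class:`SchemaError` for missing columns and
    :class:`DataError` (with 1-based data line numbers) for duplicated or
    non-monotone timestamps.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAG_COLUMNS, path)
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        line = int(bad[0]) + 2  # +1 for 0-base, +1 for header
        kind = "duplicated" if t[bad[0] + 1] == t[bad[0]] else "non-monotone"
        raise DataError(f"{path}: {kind} timestamp at data line {line}")
    dt = np.diff(t)
    fs = 1.0 / float(np.median(dt)) if dt.size else 10.0
    return TagSeries(
        t,
        df["gyro_y_rps"].to_numpy(dtype=float),
        df["speed_mps"].to_numpy(dtype=float),
        df["depth_m"].to_numpy(dtype=float),
        sampling_hz=round(fs, 6),
    )


def write_tag_series(series: TagSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": series.time_s,
            "gyro_y_rps": series.gyro_y_rps,
            "speed_mps": series.speed_mps,
            "depth_m": series.depth_m,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_lunges(path, deployment_id: str | None = None) -> list[LungeEvent]:
    df = pd.read_csv(path)
    _require_columns(df, ["deployment_id", "t_deceleration_s"], path)
    if deployment_id is not None:
        df = df[df["deployment_id"] == deployment_id]
    return [LungeEvent(float(t)) for t in df["t_deceleration_s"]]


def write_lunges(times, path, deployment_id: str = "deployment-1") -> None:
    df = pd.DataFrame(
        {"deployment_id": deployment_id, "t_deceleration_s": list(times)}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_truth(truth: SimTruth, path) -> None:
    """Truth sidecar: one row per beat plus lunge times in the header comment."""
    df = pd.DataFrame(
        {
            "t_start_s": [a for a, _ in truth.beat_boundaries],
            "t_end_s": [b for _, b in truth.beat_boundaries],
            "mode": truth.beat_modes,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# drag_coefficient_true: {truth.drag_coefficient_true!r}\n")
        fh.write(f"# lunge_times: {' '.join(f'{t:.10g}' for t in truth.lunge_times)}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_truth(path) -> SimTruth:
    cd = 0.0
    lunges: list[float] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# drag_coefficient_true:"):
            cd = float(line.split(":", 1)[1])
        elif line.startswith("# lunge_times:"):
            lunges = [float(v) for v in line.split(":", 1)[1].split()]
        elif not line.startswith("#"):
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    boundaries = list(zip(df["t_start_s"].astype(float), df["t_end_s"].astype(float)))
    return SimTruth(boundaries, list(df["mode"]), cd, lunges)


def write_morphology(morph: WhaleMorphology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(morph), fh, sort_keys=True)


def read_morphology(path) -> WhaleMorphology:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: morphology file must be a key-value mapping")
    names = {f.name for f in dataclasses.fields(WhaleMorphology)}
    missing = {"species", "body_length_m"} - set(data)
    if missing:
        raise SchemaError(f"{path}: missing morphology key(s) {', '.join(sorted(missing))}")
    return WhaleMorphology(**{k: v for k, v in data.items() if k in names})


def write_sim_config(cfg: SimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def read_sim_config(path) -> SimConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - names
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {', '.join(sorted(unknown))}")
    return SimConfig(**data)


def read_deployment(tag_path, lunges_path=None, morph_path=None):
    """Read the three deployment inputs; returns (series, lunges, morphology)."""
    series = read_tag_series(tag_path)
    lunges = read_lunges(lunges_path) if lunges_path else []
    morph = read_morphology(morph_path) if morph_path else None
    return series, lunges, morph


def write_results(
    beats: pd.DataFrame,
    summaries: pd.DataFrame | None,
    fits: pd.DataFrame | None,
    out_dir,
) -> dict[str, Path]:
    """Write per-beat, per-whale summary and fit tables to ``out_dir``.

    Column order is the order of the input frames (deterministic for
    pipeline output); floats use ``%.10g``. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in (("beats", beats), ("summaries", summaries), ("fits", fits)):
        if df is None:
            continue
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        written[name] = path
    return written
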