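"""Reading and writing trials, events, metrics tables and run configs.

All on-disk formats are delimited text: trials as two-column TSV
(``time_s``, ``accel``) or a headerless single acceleration column with the
sampling rate supplied separately; events as TSV with ``event_type``
(IC|FC), ``time_s`` and ``source``; metrics and optima as TSV tables;
cohort manifests as TSV.  Write-then-read round-trips preserve values to
full precision and malformed rows are rejected with line-numbered errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import AccelTrial, GaitEvents
from .signal import Signal, resample_linear

__all__ = [
    "RunConfig",
    "load_config",
    "read_trial",
    "write_trial",
    "read_events",
    "write_events",
    "write_metrics",
    "read_metrics",
    "write_manifest",
    "read_manifest",
    "resample_linear",
]

METRICS_COLUMNS = [
    "scale", "event_type", "tp", "fp", "fn",
    "sensitivity", "precision", "f1", "rmse_s", "rmse_n", "t_cost",
]


@dataclass
class RunConfig:
    """Run-wide processing parameters, loadable from a YAML mapping.

    CLI flags override file values.  ``fs_target`` is the analysis
    sampling rate every trial is linearly resampled to before detection.
    """

    fs_target: float = 250.0
    tolerance_s: float = 0.050
    scale_min: int = 1
    scale_max: int = 100
    axis_sign: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs_target > 0:
            raise ValueError("fs_target must be positive")
        if not self.tolerance_s > 0:
            raise ValueError("tolerance_s must be positive")
        if not 1 <= self.scale_min <= self.scale_max:
            raise ValueError("scale range must be non-empty with scale_min >= 1")

    @property
    def scales(self) -> range:
        return range(self.scale_min, self.scale_max + 1)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides
    (``None`` overrides are ignored; explicit flags win over the file)."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _sniff_delimiter(path: Path) -> str:
    """Delimiter of the first non-comment line: tab, comma or whitespace."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                if "\t" in line:
                    return "\t"
                if "," in line:
                    return ","
                return r"\s+"
    raise ValueError(f"{path}: file is empty")


def write_trial(trial: AccelTrial, path: str | Path) -> None:
    """Write a trial as two-column TSV (time_s, accel) at full precision."""
    sig = trial.accel
    df = pd.DataFrame({"time_s": sig.times, "accel": sig.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trial(
    path: str | Path,
    fs: float | None = None,
    subject_id: str = "",
    condition: str = "",
    trial_id: str = "",
) -> AccelTrial:
    """Read a trial from delimited text (TSV or CSV).

    Accepts either a ``time_s``/``time`` + ``accel`` header, or a
    headerless single acceleration column (then ``fs`` is required).  The
    time column must be uniformly sampled.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    kw = dict(sep=sep, comment="#")
    if sep != r"\s+":  # regex separators force the python engine
        kw["float_precision"] = "round_trip"
    df = pd.read_csv(path, **kw)
    cols = [str(c).strip().lower() for c in df.columns]
    df.columns = cols
    time_col = next((c for c in ("time_s", "time", "t") if c in cols), None)
    if time_col is not None:
        if "accel" not in cols:
            raise ValueError(f"{path}: found a time column but no 'accel' column")
        t = df[time_col].to_numpy(dtype=float)
        x = df["accel"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        if np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12:
            raise ValueError(f"{path}: time column is not uniformly sampled")
        sig = Signal(x, fs=1.0 / float(np.median(dt)), t0=float(t[0]))
    else:
        # headerless single column: pandas consumed the first value as header
        raw = pd.read_csv(path, header=None, **kw)
        if raw.shape[1] != 1:
            raise ValueError(
                f"{path}: expected columns (time_s, accel) or a single "
                f"acceleration column, got {raw.shape[1]} columns"
            )
        if fs is None:
            raise ValueError(f"{path}: single-column trial needs an explicit sampling rate")
        sig = Signal(raw[0].to_numpy(dtype=float), fs=fs)
    return AccelTrial(accel=sig, subject_id=subject_id, condition=condition, trial_id=trial_id)


def write_events(events: GaitEvents, path: str | Path) -> None:
    """Write events as TSV with columns event_type, time_s, source."""
    rows = [("IC", t, events.source) for t in events.ic_times]
    rows += [("FC", t, events.source) for t in events.fc_times]
    rows.sort(key=lambda r: r[1])
    df = pd.DataFrame(rows, columns=["event_type", "time_s", "source"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(
    path: str | Path,
    source: str | None = None,
    trial_span: tuple | None = None,
) -> GaitEvents:
    """Read and validate an event TSV.

    Raises line-numbered errors for unknown event types, non-monotone times
    within a type, and (when ``trial_span=(t_start, t_end)`` is given)
    events outside the trial span.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"event_type", "time_s"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    ic, fc = [], []
    last = {"IC": -np.inf, "FC": -np.inf}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        ev = str(row["event_type"]).strip().upper()
        if ev not in ("IC", "FC"):
            raise ValueError(f"{path}:{line}: unknown event type {row['event_type']!r}")
        t = float(row["time_s"])
        if not np.isfinite(t):
            raise ValueError(f"{path}:{line}: non-finite event time")
        if trial_span is not None and not (trial_span[0] <= t <= trial_span[1]):
            raise ValueError(
                f"{path}:{line}: event at {t} s outside trial span {trial_span}"
            )
        if t <= last[ev]:
            raise ValueError(f"{path}:{line}: {ev} times must be strictly increasing")
        last[ev] = t
        (ic if ev == "IC" else fc).append(t)
    if source is None:
        sources = set(df["source"]) if "source" in df.columns else {"reference"}
        source = sources.pop() if len(sources) == 1 else "reference"
    return GaitEvents(ic_times=np.array(ic), fc_times=np.array(fc), source=source)


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-scale metrics table as TSV, enforcing the schema."""
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table is missing columns {missing}")
    extra = [c for c in df.columns if c not in METRICS_COLUMNS]
    df = df[extra + METRICS_COLUMNS]  # grouping keys first, schema after
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metrics table is missing columns {missing}")
    return df


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_report(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
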