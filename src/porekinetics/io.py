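"""File formats: traces (CSV/HDF5), event tables (TSV), reports (JSON),
experiment configs (TOML/YAML).

Traces round-trip bit-exactly through HDF5 and to six significant digits
through CSV.  The CSV dialect is two columns ``time_s,current_pA`` with a
header and a uniform time grid.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import EVENT_COLUMNS, EventTable
from .exceptions import FormatError
from .simulate import Trace

_JSONABLE = (str, int, float, bool, type(None))


def _sanitize(obj):
    """Coerce numpy scalars/arrays into plain JSON-serializable values."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, _JSONABLE):
        return obj
    return str(obj)


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt"):
        return "csv"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise FormatError(f"cannot infer trace format from suffix {suffix!r}")


def write_trace(trace: Trace, path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _format_of(path, fmt)
    if fmt == "csv":
        t = np.arange(len(trace.samples)) * trace.dt
        with open(path, "w") as fh:
            fh.write("time_s,current_pA\n")
            np.savetxt(fh, np.column_stack([t, trace.samples]),
                       fmt="%.8g", delimiter=",")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            g = fh.create_group("trace")
            g.create_dataset("samples", data=trace.samples)
            g.attrs["dt"] = trace.dt
            g.attrs["metadata_json"] = json.dumps(_sanitize(trace.metadata))
    else:
        raise FormatError(f"unknown trace format {fmt!r}")
    return path


def read_trace(path, fmt: str | None = None) -> Trace:
    path = Path(path)
    fmt = _format_of(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if "trace/samples" not in fh:
                raise FormatError("HDF5 file lacks /trace/samples")
            g = fh["trace"]
            samples = np.asarray(g["samples"])
            dt = float(g.attrs["dt"])
            meta = json.loads(g.attrs.get("metadata_json", "{}"))
        return Trace(samples=samples, dt=dt, metadata=meta)
    df = pd.read_csv(path)
    expected = ["time_s", "current_pA"]
    if list(df.columns) != expected:
        raise FormatError(
            f"CSV header must be {','.join(expected)!r}, got {','.join(df.columns)!r}"
        )
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise FormatError("trace CSV must contain at least two rows")
    dt = t[1] - t[0]
    if dt <= 0:
        raise FormatError("non-uniform time grid at row 2")
    bad = np.flatnonzero(np.abs(np.diff(t) - dt) > 1e-6 * max(dt, 1e-12))
    if len(bad):
        raise FormatError(f"non-uniform time grid at row {int(bad[0]) + 3}")
    return Trace(samples=df["current_pA"].to_numpy(), dt=float(dt),
                 metadata={"source": str(path)})


def write_events(events: EventTable, path) -> Path:
    path = Path(path)
    df = events.df.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    with open(meta_path, "w") as fh:
        json.dump(_sanitize({"deadtime_s": events.deadtime,
                             "metadata": events.metadata}), fh, indent=1)
    return path


def read_events(path) -> EventTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event TSV is missing column(s): {', '.join(missing)}")
    deadtime = 0.0
    metadata: dict = {}
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        deadtime = float(meta.get("deadtime_s", 0.0))
        metadata = meta.get("metadata", {})
    return EventTable(df=df[EVENT_COLUMNS], deadtime=deadtime, metadata=metadata)


def write_report(report: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_sanitize(report), fh, indent=1)
    return path


def load_config(path) -> dict:
    """Load an experiment config from TOML or YAML by file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    raise FormatError(f"unknown config format {suffix!r} (use .toml or .yaml)")
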