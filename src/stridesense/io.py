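"""Reading raw IMU logs and global-frame sprint files; writing stride tables.

Raw logs are delimited text with a header row naming the columns; a
``unit_spec`` declares the on-disk units and everything is converted to SI
on read.  Samples at or beyond the sensor's range (±16 g, ±2000 °/s for the
reference hardware) are flagged, never clipped.

Global-frame sprint files (the per-sprint deposit format: horizontal-plane
acceleration plus touch-down/toe-off instants) are read through a small
dialect registry sniffed from the file contents:

* ``csv``    — column-named CSV, optional ``# key: value`` header comments,
  optional ``event`` column with ``td``/``to`` markers (this is also the
  format the package writes);
* ``matrix`` — whitespace-delimited numeric matrix ``t ax ay az`` with an
  optional ``<stem>.events.json`` sidecar ``{"td": [...], "to": [...]}``.

New dialects can be added with :func:`register_sprint_reader`.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .types import (
    ACC_RANGE_G,
    GYR_RANGE_DPS,
    G_DEFAULT,
    GaitEvents,
    GlobalSprint,
    ImuRecording,
)

__all__ = [
    "read_raw_log",
    "read_global_sprint",
    "write_global_sprint",
    "read_stride_table",
    "write_stride_table",
    "register_sprint_reader",
]

#: float format preserving full double precision in text round-trips
_FLOAT_FMT = "%.17g"

_ACC_UNITS = {"g": None, "m/s2": 1.0, "m/s^2": 1.0}   # None -> multiply by g
_GYR_UNITS = {"deg/s": np.pi / 180.0, "rad/s": 1.0}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "samples": None}  # None -> divide by fs


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def read_raw_log(
    path,
    unit_spec: Optional[dict] = None,
    fs: Optional[float] = None,
    foot: str = "unknown",
    g: float = G_DEFAULT,
) -> ImuRecording:
    """Read a delimited raw IMU log into SI units.

    Parameters
    ----------
    unit_spec
        Mapping with keys ``acc`` (``"g"`` or ``"m/s2"``), ``gyr``
        (``"deg/s"`` or ``"rad/s"``) and ``time`` (``"s"``, ``"ms"`` or
        ``"samples"``).  Defaults assume SI with time in seconds.
    fs
        Required when the log stores sample counts instead of timestamps;
        otherwise inferred from the median timestamp interval.

    Saturated samples (|acc| ≥ 16 g or |gyr| ≥ 2000 °/s after conversion)
    are flagged per channel; gaps longer than two sample periods are
    reported with a warning.
    """
    path = Path(path)
    spec = {"acc": "m/s2", "gyr": "rad/s", "time": "s"}
    if unit_spec:
        spec.update(unit_spec)
    for key, table in (("acc", _ACC_UNITS), ("gyr", _GYR_UNITS), ("time", _TIME_UNITS)):
        if spec[key] not in table:
            raise ValueError(f"unknown {key} unit {spec[key]!r}")

    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", float_precision="round_trip")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    df.columns = [c.strip().lower() for c in df.columns]
    tcol = next((c for c in ("t", "time", "timestamp", "sample") if c in df.columns), None)
    need = ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
    missing = [c for c in ([tcol or "t"] + need) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    traw = df[tcol].to_numpy(dtype=float)
    if _TIME_UNITS[spec["time"]] is None:
        if fs is None:
            raise ValueError("fs is required when time is stored as sample counts")
        t = traw / fs
    else:
        t = traw * _TIME_UNITS[spec["time"]]
        if fs is None:
            if len(t) < 2:
                raise ValueError("cannot infer fs from a single sample")
            fs = 1.0 / float(np.median(np.diff(t)))
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    gaps = np.flatnonzero(np.diff(t) > 2.5 / fs)
    if len(gaps):
        warnings.warn(
            f"{path}: {len(gaps)} gap(s) longer than 2 sample periods "
            f"(first after sample {gaps[0]})",
            stacklevel=2,
        )

    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float)
    if _ACC_UNITS[spec["acc"]] is None:
        acc = acc * g
    gyr = gyr * _GYR_UNITS[spec["gyr"]]

    mag = None
    if all(c in df.columns for c in ("mag_x", "mag_y", "mag_z")):
        mag = df[["mag_x", "mag_y", "mag_z"]].to_numpy(dtype=float)

    acc_sat = np.abs(acc) >= ACC_RANGE_G * g - 1e-12
    gyr_sat = np.abs(gyr) >= np.deg2rad(GYR_RANGE_DPS) - 1e-12
    return ImuRecording(
        t=t, acc=acc, gyr=gyr, fs=float(fs), foot=foot, mag=mag,
        acc_saturated=acc_sat, gyr_saturated=gyr_sat,
    )


# ---------------------------------------------------------------------------
# global-frame sprint files

_SPRINT_READERS: list[tuple[str, Callable, Callable]] = []


def register_sprint_reader(name: str, sniffer: Callable, reader: Callable) -> None:
    """Register a new deposit-file dialect.

    ``sniffer(path) -> bool`` decides whether ``reader(path) -> GlobalSprint``
    applies.  Registered dialects are tried before the built-in ones.
    """
    _SPRINT_READERS.insert(0, (name, sniffer, reader))


def _read_header_comments(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("# ").split(":", 1)
                meta[k.strip().lower()] = v.strip()
    return meta


def _sniff_csv(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "acc_x" in line.lower()
    return False


def _read_csv_sprint(path: Path) -> GlobalSprint:
    meta = _read_header_comments(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    if "t" not in df.columns or "acc_x" not in df.columns or "acc_z" not in df.columns:
        raise ValueError(f"{path}: need columns t, acc_x, acc_z")
    t = df["t"].to_numpy(dtype=float)
    fs = float(meta["fs"]) if "fs" in meta else 1.0 / float(np.median(np.diff(t)))
    foot = meta.get("foot", "unknown")
    events = None
    if "event" in df.columns:
        ev = df["event"].fillna("").astype(str).str.strip().str.lower()
        td = np.flatnonzero(ev == "td")
        to = np.flatnonzero(ev == "to")
        if len(td) or len(to):
            events = GaitEvents(td=td, to=to, foot=foot)
    return GlobalSprint(
        t=t,
        acc_x=df["acc_x"].to_numpy(dtype=float),
        acc_z=df["acc_z"].to_numpy(dtype=float),
        acc_y=df["acc_y"].to_numpy(dtype=float) if "acc_y" in df.columns else None,
        fs=fs,
        foot=foot,
        events=events,
    )


def _sniff_matrix(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                toks = line.split()
                if len(toks) < 2:
                    return False
                try:
                    [float(x) for x in toks]
                    return True
                except ValueError:
                    return False
    return False


def _read_matrix_sprint(path: Path) -> GlobalSprint:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 4:
        raise ValueError(f"{path}: expected a numeric matrix with columns t ax ay az")
    t, ax, ay, az = data[:, 0], data[:, 1], data[:, 2], data[:, 3]
    fs = 1.0 / float(np.median(np.diff(t)))
    events = None
    foot = "unknown"
    sidecar = path.with_suffix(path.suffix + ".events.json")
    if not sidecar.exists():
        sidecar = path.with_name(path.stem + ".events.json")
    if sidecar.exists():
        ev = json.loads(sidecar.read_text())
        foot = ev.get("foot", "unknown")
        events = GaitEvents(
            td=np.asarray(ev.get("td", []), int),
            to=np.asarray(ev.get("to", []), int),
            foot=foot,
        )
    return GlobalSprint(t=t, acc_x=ax, acc_z=az, acc_y=ay, fs=fs, foot=foot, events=events)


def read_global_sprint(path) -> GlobalSprint:
    """Read a global-frame sprint file, sniffing the dialect.

    Raises on unparseable layouts and on event indices outside the signal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for name, sniffer, reader in _SPRINT_READERS + [
        ("csv", _sniff_csv, _read_csv_sprint),
        ("matrix", _sniff_matrix, _read_matrix_sprint),
    ]:
        if sniffer(path):
            return reader(path)
    raise ValueError(f"{path}: unrecognized global-sprint layout")


def write_global_sprint(sprint: GlobalSprint, path, provenance: str = "") -> None:
    """Write a sprint in the package's CSV dialect (full double precision)."""
    path = Path(path)
    n = len(sprint)
    event = np.full(n, "", dtype=object)
    if sprint.events is not None:
        event[sprint.events.td] = "td"
        event[sprint.events.to] = "to"
    df = pd.DataFrame(
        {
            "t": sprint.t,
            "acc_x": sprint.acc_x,
            "acc_y": np.zeros(n) if sprint.acc_y is None else sprint.acc_y,
            "acc_z": sprint.acc_z,
            "event": event,
        }
    )
    with open(path, "w") as fh:
        fh.write("# stridesense global sprint v1\n")
        fh.write(f"# fs: {sprint.fs!r}\n")
        fh.write(f"# foot: {sprint.foot}\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_stride_table(table: pd.DataFrame, path, provenance: str = "") -> None:
    """Write a stride table as CSV; re-reading reproduces all numeric values.

    An empty table produces a header-only file with a warning.
    """
    if len(table) == 0:
        warnings.warn("writing an empty stride table (header only)", stacklevel=2)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        table.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_stride_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
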