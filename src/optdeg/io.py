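"""Readings and sensor-layout I/O.

Two plain CSV formats, comma-separated, UTF-8, "." decimal:

``readings.csv``: ``timestamp,sensor_id,T,RH[,light]`` -- one row per
time-stamped measurement.  Timestamps are ISO-8601 without timezone and are
interpreted as greenhouse local wall-clock time.  T in degC, RH in %,
light (optional) in lux.

``layout.csv``: ``sensor_id,x,y,height[,section]`` -- sensor positions in
metres, origin at the south-west corner, x east-positive, y north-positive,
height above ground.

Malformed rows in readings files are rejected row-by-row with a logged
reason (strict mode raises instead); structural problems (missing columns,
duplicate sensor ids in a layout) always raise :class:`FormatError`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["FormatError", "read_readings", "read_layout", "write_records"]

log = logging.getLogger(__name__)

READING_COLUMNS = ["timestamp", "sensor_id", "T", "RH"]
LAYOUT_COLUMNS = ["sensor_id", "x", "y", "height"]


class FormatError(ValueError):
    """A file violates the documented tabular format."""


def read_readings(path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a readings CSV.

    Returns a DataFrame with columns ``timestamp`` (datetime64),
    ``sensor_id`` (str), ``T``, ``RH`` and, when present in the file,
    ``light``, sorted by (sensor_id, timestamp).  Rows with unparseable
    timestamps/numbers, RH outside [0, 100] or duplicate
    (timestamp, sensor_id) keys are dropped and logged; ``strict=True``
    raises on the first bad row instead.  The number of rejected rows is
    available as ``df.attrs["n_rejected"]``.
    """
    raw = pd.read_csv(path, dtype={"sensor_id": str},
                      float_precision="round_trip")
    missing = [c for c in READING_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"readings file {path} missing column(s): {missing}")

    has_light = "light" in raw.columns
    rejected = 0

    def _reject(mask: pd.Series, reason: str) -> pd.Series:
        nonlocal rejected
        n = int(mask.sum())
        if n:
            if strict:
                first = raw.index[mask][0]
                raise FormatError(f"row {first}: {reason}")
            log.warning("rejected %d row(s): %s", n, reason)
            rejected += n
        return ~mask

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    keep = _reject(ts.isna(), "unparseable timestamp")
    t = pd.to_numeric(raw["T"], errors="coerce")
    keep &= _reject(t.isna() | ~np.isfinite(t), "unparseable T")
    rh = pd.to_numeric(raw["RH"], errors="coerce")
    keep &= _reject(rh.isna() | ~np.isfinite(rh), "unparseable RH")
    keep &= _reject(rh.notna() & ((rh < 0) | (rh > 100)), "RH out of range")

    df = pd.DataFrame({"timestamp": ts, "sensor_id": raw["sensor_id"],
                       "T": t, "RH": rh})
    if has_light:
        df["light"] = pd.to_numeric(raw["light"], errors="coerce")
    df = df[keep]

    dup = df.duplicated(subset=["timestamp", "sensor_id"], keep="first")
    if dup.any():
        if strict:
            raise FormatError("duplicate (timestamp, sensor_id) rows")
        log.warning("rejected %d duplicate (timestamp, sensor_id) row(s)",
                    int(dup.sum()))
        rejected += int(dup.sum())
        df = df[~dup]

    df = df.sort_values(["sensor_id", "timestamp"], kind="mergesort")
    df = df.reset_index(drop=True)
    df.attrs["n_rejected"] = rejected
    return df


def read_layout(path) -> pd.DataFrame:
    """Read and validate a sensor-layout CSV.

    Returns a DataFrame with columns ``sensor_id`` (str), ``x``, ``y``,
    ``height`` and, when present, ``section``.  Duplicate sensor ids,
    negative coordinates or non-positive heights raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path, dtype={"sensor_id": str},
                     float_precision="round_trip")
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"layout file {path} missing column(s): {missing}")
    if df["sensor_id"].duplicated().any():
        dups = df.loc[df["sensor_id"].duplicated(), "sensor_id"].tolist()
        raise FormatError(f"duplicate sensor_id(s) in layout: {dups}")
    for col in ("x", "y", "height"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if len(df):
        if (df[["x", "y"]] < 0).any().any():
            raise FormatError("layout coordinates must be non-negative")
        if (df["height"] <= 0).any():
            raise FormatError("layout heights must be positive")
    keep = LAYOUT_COLUMNS + (["section"] if "section" in df.columns else [])
    return df[keep].reset_index(drop=True)


def write_records(path, records: pd.DataFrame) -> None:
    """Write a homogeneous record table as CSV at full float precision.

    Floats are written with 17 significant digits so that reading the
    file back reproduces the values bit-for-bit.
    """
    records.to_csv(path, index=False, float_format="%.17g")
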