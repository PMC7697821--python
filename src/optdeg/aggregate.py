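"""Temporal aggregation: light classes, day/night periods, hourly means,
descriptive statistics and a local-polynomial kernel smoother.

Conventions (all overridable through :class:`LightThresholds` or function
arguments):

* Light classification from a lux reading: night below ``night_lux``
  (default 10 lux), sun at or above ``sun_lux`` (default 10,000 lux, a
  conventional overcast/direct-sun boundary), cloud in between.  Without a
  lux reading the clock decides: sun inside the configured sun window
  (default 06:30-18:30), night outside, no cloud class.
* Day/night periods follow the light classes (day = sun or cloud), so the
  day/night statistics track actual sun presence rather than fixed clock
  hours.
* Hourly windows are label-exclusive at the start and inclusive at the end:
  the mean labelled 07:00 averages samples in (06:00, 07:00].
* Standard deviations are sample SDs (ddof=1); single-sample groups report
  sd = 0 with ``n = 1`` flagging the degeneracy, keeping tabular output
  well-formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import time as dtime

import numpy as np
import pandas as pd

__all__ = [
    "LightThresholds",
    "classify_light",
    "split_periods",
    "hourly_mean",
    "describe",
    "smooth_series",
]

log = logging.getLogger(__name__)

PERIODS = ("day", "night", "h24")


def _parse_clock(t) -> dtime:
    if isinstance(t, dtime):
        return t
    h, m = str(t).split(":")
    return dtime(int(h), int(m))


@dataclass(frozen=True)
class LightThresholds:
    """Thresholds of the sun/cloud/night classifier.

    ``night_lux``/``sun_lux`` apply when a lux reading is present;
    ``sun_window`` is the clock fallback (start, end as "HH:MM") used when
    it is not.  The window should follow the season's day length.
    """

    night_lux: float = 10.0
    sun_lux: float = 10_000.0
    sun_window: tuple = ("06:30", "18:30")

    def window_times(self) -> tuple[dtime, dtime]:
        return _parse_clock(self.sun_window[0]), _parse_clock(self.sun_window[1])


def classify_light(readings: pd.DataFrame,
                   thresholds: LightThresholds = LightThresholds()
                   ) -> pd.Series:
    """Label each reading sun/cloud/night.

    Readings with a finite ``light`` (lux) value are classified by the lux
    thresholds; the rest by the clock window (sun inside, night outside --
    the clock rule cannot distinguish cloud).
    """
    n = len(readings)
    out = pd.Series(pd.NA, index=readings.index, dtype="object")

    if "light" in readings.columns:
        lux = pd.to_numeric(readings["light"], errors="coerce")
        has = lux.notna() & np.isfinite(lux)
        out[has & (lux < thresholds.night_lux)] = "night"
        out[has & (lux >= thresholds.sun_lux)] = "sun"
        out[has & out.isna()] = "cloud"
    remaining = out.isna()
    if remaining.any():
        start, end = thresholds.window_times()
        clock = pd.to_datetime(readings.loc[remaining, "timestamp"]).dt.time
        in_window = clock.map(lambda t: start <= t < end)
        out[remaining] = np.where(in_window, "sun", "night")
    return out.astype(str)


def split_periods(light_labels: pd.Series) -> pd.Series:
    """Map light classes onto day/night periods: day = sun or cloud."""
    return pd.Series(np.where(light_labels.eq("night"), "night", "day"),
                     index=light_labels.index)


def hourly_mean(records: pd.DataFrame, variables,
                by: tuple = ("sensor_id",)) -> pd.DataFrame:
    """Hourly means over (H-1:00, H:00] windows, labelled by the window end.

    Returns a long DataFrame ``(hour, *by, variable, mean, n)``.  Windows
    without samples are omitted (and counted in a debug log); a sample
    falling exactly on the hour belongs to the window it closes.
    """
    if isinstance(variables, str):
        variables = [variables]
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    grouper = [*by, pd.Grouper(key="timestamp", freq="1h",
                               closed="right", label="right")]
    agg = df.groupby(grouper, observed=True)[list(variables)].agg(
        ["mean", "count"])
    rows = []
    for var in variables:
        sub = agg[var].reset_index().rename(
            columns={"timestamp": "hour", "count": "n"})
        sub["variable"] = var
        empty = sub["n"] == 0
        if empty.any():
            log.debug("omitting %d empty hourly window(s) for %s",
                      int(empty.sum()), var)
            sub = sub[~empty]
        rows.append(sub[["hour", *by, "variable", "mean", "n"]])
    out = pd.concat(rows, ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out


def describe(records: pd.DataFrame, periods: pd.Series,
             variables, group_keys: tuple = ()) -> pd.DataFrame:
    """Table-style descriptive statistics per variable x period x group.

    ``periods`` assigns day/night per row; the h24 period covers all rows.
    Returns a DataFrame ``(variable, period, *group_keys, mean, sd, min,
    max, range, n)`` with sample SD (ddof=1; 0 when n = 1).  Empty groups
    are simply absent.
    """
    if isinstance(variables, str):
        variables = [variables]
    group_keys = tuple(group_keys)
    frames = []
    base = records.copy()
    base["_period"] = periods.values
    for plabel in PERIODS:
        sub = base if plabel == "h24" else base[base["_period"] == plabel]
        if sub.empty:
            log.debug("period %s empty -- omitted", plabel)
            continue
        if group_keys:
            grouped = sub.groupby(list(group_keys), observed=True)
        else:
            grouped = [((), sub)]
        for key, g in grouped:
            if not isinstance(key, tuple):
                key = (key,)
            for var in variables:
                vals = g[var].to_numpy(dtype=float)
                n = len(vals)
                sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
                frames.append({
                    "variable": var, "period": plabel,
                    **dict(zip(group_keys, key)),
                    "mean": float(np.mean(vals)), "sd": sd,
                    "min": float(np.min(vals)), "max": float(np.max(vals)),
                    "range": float(np.max(vals) - np.min(vals)), "n": n,
                })
    cols = ["variable", "period", *group_keys,
            "mean", "sd", "min", "max", "range", "n"]
    return pd.DataFrame(frames, columns=cols)


def smooth_series(t, y, bandwidth: float, degree: int = 2):
    """Local-polynomial regression with a Gaussian exp(-(dt/bw)^2) kernel.

    At each target point a weighted least-squares polynomial of ``degree``
    is fitted to the neighbouring samples (weights exp(-(dt/bandwidth)^2),
    support truncated at |dt| <= 4 bandwidths for speed) and evaluated at
    the point.  A point with fewer than ``degree + 1`` samples within one
    bandwidth is passed through unsmoothed and flagged.

    Parameters
    ----------
    t : array-like
        Sample positions (numeric; for timestamps pass e.g. epoch minutes).
    y : array-like
        Sample values.
    bandwidth : float
        Kernel bandwidth in the units of ``t`` (> 0).

    Returns
    -------
    smoothed : ndarray
    passthrough : ndarray of bool
        True where the point lacked local support and was passed through.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    n = len(t)
    order = np.argsort(t, kind="mergesort")
    ts, ys = t[order], y[order]
    out = np.empty(n)
    flag = np.zeros(n, dtype=bool)
    reach = 4.0 * bandwidth
    lo = np.searchsorted(ts, ts - reach, side="left")
    hi = np.searchsorted(ts, ts + reach, side="right")
    for i in range(n):
        dt = ts[lo[i]:hi[i]] - ts[i]
        yy = ys[lo[i]:hi[i]]
        support = np.count_nonzero(np.abs(dt) <= bandwidth)
        if support < degree + 1:
            out[i] = ys[i]
            flag[i] = True
            continue
        w = np.exp(-((dt / bandwidth) ** 2))
        # polyfit in centred coordinates; value at the target is the
        # constant coefficient
        coeffs = np.polyfit(dt, yy, deg=degree, w=np.sqrt(w))
        out[i] = coeffs[-1]
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return out[inv], flag[inv]
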