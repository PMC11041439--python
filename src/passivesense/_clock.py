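"""Calendar-day helpers: timezone-aware day bounds and local-time fields."""

from __future__ import annotations

from datetime import date, datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

MS_PER_S = 1000
MS_PER_DAY = 86_400_000


def day_bounds_ms(day: date, tz: str = "UTC") -> tuple:
    """Epoch-ms [start, end) of a calendar day in the given timezone."""
    zone = ZoneInfo(tz)
    start = datetime(day.year, day.month, day.day, tzinfo=zone)
    end = start + timedelta(days=1)
    return int(start.timestamp() * MS_PER_S), int(end.timestamp() * MS_PER_S)


def local_dates(t_ms, tz: str = "UTC") -> np.ndarray:
    """Local calendar date of each epoch-ms timestamp."""
    idx = pd.to_datetime(np.asarray(t_ms, dtype="int64"), unit="ms", utc=True)
    return idx.tz_convert(tz).date


def local_hours(t_ms, tz: str = "UTC") -> np.ndarray:
    """Local hour-of-day (0..23) of each epoch-ms timestamp."""
    idx = pd.to_datetime(np.asarray(t_ms, dtype="int64"), unit="ms", utc=True)
    return idx.tz_convert(tz).hour.to_numpy()


def covered_dates(t_ms, tz: str = "UTC") -> list:
    """Sorted unique local dates covered by the timestamps.

    Timestamps are quantized to 15-minute bins before conversion (day
    boundaries are at worst 45-minute-offset aligned in any timezone), so
    this stays fast on multi-million-sample streams.
    """
    t = np.asarray(t_ms, dtype="int64")
    if len(t) == 0:
        return []
    q = np.unique(t // 900_000) * 900_000
    return sorted(set(local_dates(q, tz)))


def slice_day(df: pd.DataFrame, day: date, tz: str = "UTC") -> pd.DataFrame:
    """Rows of a time-sorted stream falling inside one local calendar day."""
    start, end = day_bounds_ms(day, tz)
    t = df["t"].to_numpy()
    lo = np.searchsorted(t, start, side="left")
    hi = np.searchsorted(t, end, side="left")
    return df.iloc[lo:hi]
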