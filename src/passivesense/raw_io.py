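"""Raw sensor-log data model and per-sensor CSV I/O.

Each sensor source is stored as a separate plain-text CSV file with a
header row and epoch-millisecond timestamps:

========  =============================  ==========================
kind      file                           columns
========  =============================  ==========================
accel     accel.csv                      t, ax, ay, az
gps       gps.csv                        t, lat, lon, accuracy
calls     calls.csv                      t, direction, duration_s
screen    screen.csv                     t, state
apps      apps.csv                       t, app_id, kb
sms       sms.csv                        t, direction
========  =============================  ==========================

In memory each stream is a :class:`pandas.DataFrame` with exactly those
columns, time-sorted.  Lightweight record dataclasses are provided for
single-row construction and for property-based testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_KINDS = ("accel", "gps", "calls", "screen", "apps", "sms")

CALL_DIRECTIONS = ("incoming", "outgoing", "missed")
SCREEN_STATES = ("on", "off")
SMS_DIRECTIONS = ("incoming", "outgoing")


class StreamFormatError(ValueError):
    """File-level problem: unknown kind, bad header, unreadable path."""


class RecordError(ValueError):
    """Row-level problem; message carries the 1-based line number."""


# ---------------------------------------------------------------------------
# Record dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccelSample:
    """One accelerometer sample: epoch ms and per-axis m/s^2."""

    t: int
    ax: float
    ay: float
    az: float


@dataclass(frozen=True)
class GpsFix:
    """One GPS fix; ``accuracy`` (m) may be absent (None)."""

    t: int
    lat: float
    lon: float
    accuracy: Optional[float] = None


@dataclass(frozen=True)
class CallRecord:
    """Call-log entry; ``t`` is call start, duration in seconds."""

    t: int
    direction: str
    duration_s: float


@dataclass(frozen=True)
class ScreenEvent:
    t: int
    state: str


@dataclass(frozen=True)
class AppUsageRecord:
    """Kilobytes exchanged by ``app_id`` since its previous report."""

    t: int
    app_id: str
    kb: float


@dataclass(frozen=True)
class SmsRecord:
    t: int
    direction: str


_RECORD_TYPES = {
    "accel": AccelSample,
    "gps": GpsFix,
    "calls": CallRecord,
    "screen": ScreenEvent,
    "apps": AppUsageRecord,
    "sms": SmsRecord,
}

_COLUMNS = {kind: tuple(f.name for f in dc_fields(t)) for kind, t in _RECORD_TYPES.items()}

_STRING_COLUMNS = {"direction", "state", "app_id"}


def columns_for(kind: str) -> tuple:
    _check_kind(kind)
    return _COLUMNS[kind]


def _check_kind(kind: str) -> None:
    if kind not in SOURCE_KINDS:
        raise StreamFormatError(
            f"unknown source kind {kind!r}; expected one of {SOURCE_KINDS}"
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _row_errors(kind: str, df: pd.DataFrame) -> pd.Series:
    """Return a string Series (index-aligned) with the first validation
    failure per row, empty string when the row is valid."""
    msg = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, text: str) -> None:
        sel = mask & (msg == "")
        msg[sel] = text

    if kind == "accel":
        bad = ~np.isfinite(df[["ax", "ay", "az"]].to_numpy(dtype=float)).all(axis=1)
        flag(pd.Series(bad, index=df.index), "non-finite acceleration value")
    elif kind == "gps":
        flag(~df["lat"].between(-90.0, 90.0), "lat outside [-90, 90]")
        flag(~df["lon"].between(-180.0, 180.0), "lon outside [-180, 180]")
    elif kind == "calls":
        flag(~df["direction"].isin(CALL_DIRECTIONS),
             f"direction not in {CALL_DIRECTIONS}")
        flag(df["duration_s"] < 0, "duration_s < 0")
        flag((df["direction"] == "missed") & (df["duration_s"] != 0),
             "missed call with nonzero duration")
    elif kind == "screen":
        flag(~df["state"].isin(SCREEN_STATES), f"state not in {SCREEN_STATES}")
    elif kind == "apps":
        flag(df["kb"] < 0, "kb < 0")
        flag(df["app_id"].astype(str).str.len() == 0, "empty app_id")
    elif kind == "sms":
        flag(~df["direction"].isin(SMS_DIRECTIONS),
             f"direction not in {SMS_DIRECTIONS}")
    return msg


def validate_frame(df: pd.DataFrame, kind: str) -> None:
    """Raise :class:`RecordError` on the first invalid row."""
    errors = _row_errors(kind, df)
    bad = errors[errors != ""]
    if len(bad):
        i = bad.index[0]
        raise RecordError(f"row {i}: {bad.iloc[0]}")


def empty_frame(kind: str) -> pd.DataFrame:
    _check_kind(kind)
    cols = _COLUMNS[kind]
    data = {}
    for c in cols:
        if c == "t":
            data[c] = pd.Series([], dtype="int64")
        elif c in _STRING_COLUMNS:
            data[c] = pd.Series([], dtype=object)
        else:
            data[c] = pd.Series([], dtype=float)
    return pd.DataFrame(data)


def records_to_frame(records: Sequence, kind: str) -> pd.DataFrame:
    """Convert a list of record dataclasses into the canonical DataFrame."""
    _check_kind(kind)
    if not len(records):
        return empty_frame(kind)
    df = pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records],
                      columns=_COLUMNS[kind])
    return _coerce_dtypes(df, kind)


def frame_to_records(df: pd.DataFrame, kind: str) -> list:
    _check_kind(kind)
    rtype = _RECORD_TYPES[kind]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if kind == "gps" and ("accuracy" in d) and pd.isna(d["accuracy"]):
            d["accuracy"] = None
        out.append(rtype(**d))
    return out


def _coerce_dtypes(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    df = df.copy()
    df["t"] = df["t"].astype("int64")
    for c in _COLUMNS[kind]:
        if c == "t" or c in _STRING_COLUMNS:
            continue
        df[c] = df[c].astype(float)
    return df


# ---------------------------------------------------------------------------
# Read / write
# ---------------------------------------------------------------------------

def _to_numeric_exact(raw: pd.Series) -> pd.Series:
    """Parse strings to float64 with correctly rounded (round-trip-exact)
    conversion; unparseable entries become NaN."""
    arr = raw.to_numpy()
    try:
        return pd.Series(arr.astype(np.float64), index=raw.index)
    except (TypeError, ValueError):
        out = np.empty(len(arr))
        for i, v in enumerate(arr):
            try:
                out[i] = float(v)
            except (TypeError, ValueError):
                out[i] = np.nan
        return pd.Series(out, index=raw.index)


def read_stream(path, source_kind: str, on_invalid: str = "raise") -> pd.DataFrame:
    """Read one sensor CSV into a validated, time-sorted DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row matching the kind's schema.
    source_kind
        One of :data:`SOURCE_KINDS`.
    on_invalid
        ``"raise"`` (default) aborts on the first invalid row with its
        line number; ``"drop"`` removes invalid rows, logs the count and
        records it in ``frame.attrs["n_dropped"]``.

    Out-of-order rows are sorted (stable) with a logged warning; the
    reader never silently drops a well-formed row.
    """
    _check_kind(source_kind)
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    path = Path(path)
    if not path.exists():
        raise StreamFormatError(f"no such file: {path}")

    cols = _COLUMNS[source_kind]
    try:
        df = pd.read_csv(path, dtype={c: object for c in cols})
    except pd.errors.EmptyDataError:
        raise StreamFormatError(f"{path}: empty file (missing header)") from None
    if tuple(df.columns) != cols:
        raise StreamFormatError(
            f"{path}: header {tuple(df.columns)} does not match "
            f"{source_kind!r} schema {cols}"
        )

    # Parse columns; track per-row parse failures (line = index + 2: header+1-based).
    parse_err = pd.Series("", index=df.index, dtype=object)
    parsed = {}
    for c in cols:
        raw = df[c]
        if c in _STRING_COLUMNS:
            parsed[c] = raw.astype(str)
            continue
        num = _to_numeric_exact(raw)
        missing_ok = source_kind == "gps" and c == "accuracy"
        bad = num.isna() & raw.notna() if missing_ok else num.isna()
        parse_err[bad & (parse_err == "")] = f"unparseable value in column {c!r}"
        parsed[c] = num
    out = pd.DataFrame(parsed, columns=list(cols))

    valid_err = _row_errors(source_kind, out.fillna({c: 0 for c in cols if c == "t"}))
    err = parse_err.where(parse_err != "", valid_err)
    bad_idx = err[err != ""]
    n_dropped = 0
    if len(bad_idx):
        if on_invalid == "raise":
            i = bad_idx.index[0]
            raise RecordError(f"{path}, line {i + 2}: {bad_idx.iloc[0]}")
        n_dropped = len(bad_idx)
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
        out = out[err == ""]

    out = _coerce_dtypes(out.reset_index(drop=True), source_kind)
    if not out["t"].is_monotonic_increasing:
        logger.warning("%s: rows out of time order; sorting", path)
        out = out.sort_values("t", kind="stable").reset_index(drop=True)
    out.attrs["kind"] = source_kind
    out.attrs["n_dropped"] = n_dropped
    return out


def write_stream(records, path, source_kind: Optional[str] = None) -> Path:
    """Write records (DataFrame or record list) to a sensor CSV.

    Records are validated against the type invariants before anything is
    written, so an invalid input leaves no file behind.  Round-trip
    contract: ``read_stream(write_stream(x)) == x``.
    """
    if isinstance(records, pd.DataFrame):
        kind = source_kind or records.attrs.get("kind")
        if kind is None:
            raise StreamFormatError("source_kind required for a bare DataFrame")
        df = _coerce_dtypes(records[list(_COLUMNS[kind])].copy(), kind)
    else:
        if source_kind is None:
            if len(records):
                kind = {v: k for k, v in _RECORD_TYPES.items()}[type(records[0])]
            else:
                raise StreamFormatError("source_kind required for an empty list")
        else:
            kind = source_kind
        df = records_to_frame(records, kind)
    _check_kind(kind)
    validate_frame(df, kind)
    if not df["t"].is_monotonic_increasing:
        raise RecordError("records not sorted by t")
    path = Path(path)
    # repr() is the shortest exact representation of a float64; pandas'
    # default float formatting does not round-trip the last digit.
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def normalize_screen_events(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated same-state screen events to the first occurrence
    so that consecutive events strictly alternate on/off."""
    if not len(events):
        return events.reset_index(drop=True)
    keep = events["state"].ne(events["state"].shift())
    return events[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# SensorStreams container
# ---------------------------------------------------------------------------

STREAM_FILES = {kind: f"{kind}.csv" for kind in SOURCE_KINDS}


@dataclass
class SensorStreams:
    """A user's per-source sensor streams plus the timezone used to cut
    calendar days."""

    user_id: str
    accel: pd.DataFrame = field(default_factory=lambda: empty_frame("accel"))
    gps: pd.DataFrame = field(default_factory=lambda: empty_frame("gps"))
    calls: pd.DataFrame = field(default_factory=lambda: empty_frame("calls"))
    screen: pd.DataFrame = field(default_factory=lambda: empty_frame("screen"))
    apps: pd.DataFrame = field(default_factory=lambda: empty_frame("apps"))
    sms: pd.DataFrame = field(default_factory=lambda: empty_frame("sms"))
    day_boundary_tz: str = "UTC"

    def __post_init__(self):
        if not self.user_id:
            raise ValueError("user_id must be nonempty")
        for kind in SOURCE_KINDS:
            df = self.get(kind)
            if len(df) and not df["t"].is_monotonic_increasing:
                raise ValueError(f"{kind} stream not time-sorted")

    def get(self, kind: str) -> pd.DataFrame:
        _check_kind(kind)
        return getattr(self, kind)

    def replace(self, kind: str, df: pd.DataFrame) -> "SensorStreams":
        _check_kind(kind)
        kwargs = {k: getattr(self, k) for k in SOURCE_KINDS}
        kwargs[kind] = df
        return SensorStreams(user_id=self.user_id,
                             day_boundary_tz=self.day_boundary_tz, **kwargs)

    def time_span(self) -> Optional[tuple]:
        """(min t, max t) in epoch ms over all nonempty streams, or None."""
        lo, hi = math.inf, -math.inf
        for kind in SOURCE_KINDS:
            df = self.get(kind)
            if len(df):
                lo = min(lo, int(df["t"].iloc[0]))
                hi = max(hi, int(df["t"].iloc[-1]))
        if lo is math.inf:
            return None
        return int(lo), int(hi)


def write_streams(streams: SensorStreams, outdir) -> Path:
    """Write every stream of a user as one CSV per source."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind in SOURCE_KINDS:
        write_stream(streams.get(kind), outdir / STREAM_FILES[kind], kind)
    return outdir


def read_streams(indir, user_id: str = "user", day_boundary_tz: str = "UTC",
                 on_invalid: str = "raise") -> SensorStreams:
    """Read a directory of per-sensor CSVs; missing files read as empty."""
    indir = Path(indir)
    kwargs = {}
    for kind in SOURCE_KINDS:
        p = indir / STREAM_FILES[kind]
        kwargs[kind] = read_stream(p, kind, on_invalid) if p.exists() else empty_frame(kind)
    return SensorStreams(user_id=user_id, day_boundary_tz=day_boundary_tz, **kwargs)
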