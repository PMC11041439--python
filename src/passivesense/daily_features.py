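"""Per-calendar-day behavioral features from calls, screen, app traffic
and accelerometer streams.

Feature families and naming:

* calls: ``mean_incoming``, ``mean_outgoing``, ``tot_call_length``,
  ``outgoing_call`` (missed calls are excluded from all of them)
* screen: ``mean_time_usage``, ``number_switch_on``, ``b_1``..``b_24``
  (seconds of use per local hour slot; ``b_n`` covers hour n-1 to n)
* apps: ``tot_kb_social``, ``tot_kb_communication``, ``tot_kb_navigation``,
  ``tot_kb``
* activity: ``m_amp_1``..``m_amp_24`` (mean acceleration amplitude),
  ``s_a_1``..``s_a_24`` / ``s_r_1``..``s_r_24`` (seconds of high / low
  activity per hour slot), ``percentage_activity``

Features whose denominator is empty (no incoming calls, no sessions, no
samples in an hour slot) are reported as *missing* rather than zero; the
anomaly stage decides imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._clock import covered_dates, day_bounds_ms, local_hours, slice_day
from .raw_io import SensorStreams, normalize_screen_events

GRAVITY = 9.81

#: Table-driven app categorization; a record counts toward a category when
#: any keyword is a substring of its lowercased app id.
DEFAULT_APP_CATEGORIES: Dict[str, Tuple[str, ...]] = {
    "social": ("facebook", "instagram", "twitter", "linkedin"),
    "communication": ("whatsapp", "messenger", "telegram", "skype", "hangouts"),
    "navigation": ("chrome", "firefox", "browser", "google", "youtube",
                   "tripadvisor"),
}

_HOURLY_FAMILIES = ("b", "m_amp", "s_a", "s_r")

SCALAR_FEATURES = (
    "mean_incoming", "mean_outgoing", "tot_call_length", "outgoing_call",
    "mean_time_usage", "number_switch_on",
    "tot_kb_social", "tot_kb_communication", "tot_kb_navigation", "tot_kb",
    "percentage_activity",
)


def feature_names() -> List[str]:
    names = list(SCALAR_FEATURES)
    for fam in _HOURLY_FAMILIES:
        names += [f"{fam}_{n}" for n in range(1, 25)]
    return names


@dataclass
class FeatureDay:
    """One calendar day's feature vector; ``missing`` lists feature names
    whose value is undefined for this day (kept NaN in ``values``)."""

    day: date
    values: Dict[str, float]
    missing: FrozenSet[str]

    def get(self, name: str) -> float:
        return self.values[name]


def _result(values: Dict[str, float], missing: Iterable[str]) -> Tuple[dict, frozenset]:
    missing = frozenset(missing)
    for name in missing:
        values[name] = float("nan")
    return values, missing


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

def call_features(calls: pd.DataFrame, day: date, tz: str = "UTC"
                  ) -> Tuple[Dict[str, float], FrozenSet[str]]:
    """Call aggregates for one day; missed calls are ignored entirely."""
    sub = slice_day(calls, day, tz)
    inc = sub[sub["direction"] == "incoming"]["duration_s"]
    out = sub[sub["direction"] == "outgoing"]["duration_s"]
    values = {
        "tot_call_length": float(inc.sum() + out.sum()),
        "outgoing_call": float(len(out)),
    }
    missing = []
    for name, series in (("mean_incoming", inc), ("mean_outgoing", out)):
        if len(series):
            values[name] = float(series.mean())
        else:
            missing.append(name)
    return _result(values, missing)


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSession:
    """A contiguous span of screen-on time clipped to one day.

    ``started_in_day`` is False for the remainder of a session opened the
    previous day (credited from midnight).
    """

    start: int   # epoch ms
    end: int
    started_in_day: bool

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / 1000.0


def screen_sessions(events: pd.DataFrame, day: date, tz: str = "UTC"
                    ) -> List[ScreenSession]:
    """Pair on/off events into sessions, clipped at the day boundaries.

    A session open at midnight is truncated and its remainder credited to
    the next day; a day starting in the on state (off event first) gets a
    leading session counted from 00:00.
    """
    ev = normalize_screen_events(events)
    lo, hi = day_bounds_ms(day, tz)
    if not len(ev):
        return []
    t = ev["t"].to_numpy()
    states = ev["state"].to_numpy()
    neg, pos = -(2 ** 62), 2 ** 62
    # Build on-intervals over the whole event timeline; a leading off event
    # means the screen was on since before the record, a trailing on event
    # means it stayed on past the record (both clipped to the day below).
    on_ivs: List[Tuple[int, int]] = []
    on_start: Optional[int] = neg if states[0] == "off" else None
    for ti, st in zip(t, states):
        if st == "on":
            on_start = int(ti)
        elif on_start is not None:
            on_ivs.append((on_start, int(ti)))
            on_start = None
    if on_start is not None:
        on_ivs.append((on_start, pos))

    sessions = []
    for a, b in on_ivs:
        s, e = max(a, lo), min(b, hi)
        if e > s:
            sessions.append(ScreenSession(s, e, started_in_day=a >= lo))
    return sessions


def brightness_features(sessions: Sequence[ScreenSession], day: date,
                        tz: str = "UTC") -> Tuple[Dict[str, float], FrozenSet[str]]:
    """Session-duration aggregates and per-hour seconds of use ``b_n``."""
    lo, _ = day_bounds_ms(day, tz)
    values: Dict[str, float] = {f"b_{n}": 0.0 for n in range(1, 25)}
    values["number_switch_on"] = float(sum(s.started_in_day for s in sessions))
    missing = []
    if sessions:
        values["mean_time_usage"] = float(np.mean([s.duration_s for s in sessions]))
    else:
        missing.append("mean_time_usage")
    for s in sessions:
        # split the session across local hour slots
        start = s.start
        while start < s.end:
            hour = int((start - lo) // 3_600_000)
            hour = min(hour, 23)
            slot_end = lo + (hour + 1) * 3_600_000
            chunk_end = min(s.end, slot_end)
            values[f"b_{hour + 1}"] += (chunk_end - start) / 1000.0
            start = chunk_end
    return _result(values, missing)


# ---------------------------------------------------------------------------
# Apps
# ---------------------------------------------------------------------------

def categorize_app(app_id: str,
                   categories: Dict[str, Tuple[str, ...]] = DEFAULT_APP_CATEGORIES
                   ) -> Optional[str]:
    low = app_id.lower()
    for cat, keywords in categories.items():
        if any(k in low for k in keywords):
            return cat
    return None


def app_features(records: pd.DataFrame, day: date, tz: str = "UTC",
                 categories: Dict[str, Tuple[str, ...]] = DEFAULT_APP_CATEGORIES
                 ) -> Tuple[Dict[str, float], FrozenSet[str]]:
    """Per-category and total kilobytes exchanged during the day."""
    sub = slice_day(records, day, tz)
    totals = {cat: 0.0 for cat in ("social", "communication", "navigation")}
    tot = 0.0
    for app_id, kb in zip(sub["app_id"], sub["kb"]):
        tot += float(kb)
        cat = categorize_app(str(app_id), categories)
        if cat in totals:
            totals[cat] += float(kb)
    values = {f"tot_kb_{cat}": v for cat, v in totals.items()}
    values["tot_kb"] = tot
    return _result(values, [])


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def activity_features(accel: pd.DataFrame, day: date, tz: str = "UTC",
                      high_threshold: float = 0.5, gravity: float = GRAVITY
                      ) -> Tuple[Dict[str, float], FrozenSet[str]]:
    """Hourly acceleration-amplitude and high/low-activity-second features.

    Amplitude of a sample is the Euclidean norm of (ax, ay, az); its
    *dynamic* amplitude is ``|norm - gravity|``.  Each wall-clock second
    containing samples is classified high-activity when its mean dynamic
    amplitude exceeds ``high_threshold`` (m/s^2), else low.  ``m_amp_n``
    averages the raw amplitude over hour slot n; slots without samples are
    missing.
    """
    sub = slice_day(accel, day, tz)
    lo, hi = day_bounds_ms(day, tz)
    n_hours = max(1, int(round((hi - lo) / 3_600_000)))
    values: Dict[str, float] = {}
    missing: List[str] = []
    for n in range(1, 25):
        values[f"s_a_{n}"] = 0.0
        values[f"s_r_{n}"] = 0.0

    if not len(sub):
        missing += [f"m_amp_{n}" for n in range(1, 25)]
        missing.append("percentage_activity")
        return _result(values, missing)

    t = sub["t"].to_numpy()
    amp = np.sqrt(sub["ax"].to_numpy() ** 2 + sub["ay"].to_numpy() ** 2
                  + sub["az"].to_numpy() ** 2)
    dyn = np.abs(amp - gravity)
    sec = ((t - lo) // 1000).astype(np.int64)
    n_sec = n_hours * 3600

    counts = np.bincount(sec, minlength=n_sec)
    dyn_sum = np.bincount(sec, weights=dyn, minlength=n_sec)
    sampled = counts > 0
    mean_dyn = np.zeros(n_sec)
    mean_dyn[sampled] = dyn_sum[sampled] / counts[sampled]
    high = sampled & (mean_dyn > high_threshold)
    low = sampled & ~high

    sec_hour = np.minimum(np.arange(n_sec) // 3600, 23)
    s_a = np.bincount(sec_hour, weights=high.astype(float), minlength=24)
    s_r = np.bincount(sec_hour, weights=low.astype(float), minlength=24)

    hour_of_sample = np.minimum(sec // 3600, 23)
    amp_sum = np.bincount(hour_of_sample, weights=amp, minlength=24)
    amp_cnt = np.bincount(hour_of_sample, minlength=24)

    for n in range(1, 25):
        values[f"s_a_{n}"] = float(s_a[n - 1])
        values[f"s_r_{n}"] = float(s_r[n - 1])
        if amp_cnt[n - 1] > 0:
            values[f"m_amp_{n}"] = float(amp_sum[n - 1] / amp_cnt[n - 1])
        else:
            missing.append(f"m_amp_{n}")
    tot_a, tot_r = float(s_a.sum()), float(s_r.sum())
    if tot_a + tot_r > 0:
        values["percentage_activity"] = tot_a / (tot_a + tot_r)
    else:
        missing.append("percentage_activity")
    return _result(values, missing)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_feature_days(streams: SensorStreams,
                         days: Optional[Sequence[date]] = None,
                         high_threshold: float = 0.5,
                         include_gps: bool = True,
                         cluster_kwargs: Optional[dict] = None,
                         ) -> List[FeatureDay]:
    """Compute the full per-day feature vector for every covered day.

    GPS features use place clusters computed over the whole observation
    window so cluster identities (and the home place) are stable across
    days.
    """
    tz = streams.day_boundary_tz
    if days is None:
        all_t = np.concatenate([
            streams.get(k)["t"].to_numpy()
            for k in ("accel", "gps", "calls", "screen", "apps")
            if len(streams.get(k))
        ]) if streams.time_span() else np.array([], dtype="int64")
        days = covered_dates(all_t, tz)

    cluster_set = None
    if include_gps and len(streams.gps) >= 2:
        from . import gps_features
        cluster_set = gps_features.cluster_fixes(streams.gps,
                                                 **(cluster_kwargs or {}))
        if cluster_set.clusters:
            gps_features.identify_home(cluster_set, streams.gps, tz)

    out = []
    for day in days:
        values: Dict[str, float] = {}
        missing: set = set()
        for vals, miss in (
            call_features(streams.calls, day, tz),
            brightness_features(screen_sessions(streams.screen, day, tz), day, tz),
            app_features(streams.apps, day, tz),
            activity_features(streams.accel, day, tz, high_threshold),
        ):
            values.update(vals)
            missing.update(miss)
        if include_gps:
            from . import gps_features
            gvals, gmiss = gps_features.gps_day_feature_dict(
                streams.gps, cluster_set, day, tz)
            values.update(gvals)
            missing.update(gmiss)
        out.append(FeatureDay(day=day, values=values, missing=frozenset(missing)))
    return out


def feature_days_to_frame(feature_days: Sequence[FeatureDay]
                          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(values, missing-mask) DataFrames indexed by day."""
    days = [fd.day for fd in feature_days]
    names = sorted({n for fd in feature_days for n in fd.values})
    vals = pd.DataFrame(
        [[fd.values.get(n, float("nan")) for n in names] for fd in feature_days],
        index=pd.Index(days, name="day"), columns=names)
    mask = pd.DataFrame(
        [[n in fd.missing or n not in fd.values for n in names]
         for fd in feature_days],
        index=pd.Index(days, name="day"), columns=names)
    return vals, mask
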