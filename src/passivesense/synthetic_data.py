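"""Synthetic multi-week single-user smartphone streams with known ground
truth.

The simulator produces per-sensor streams (accelerometer, GPS, calls,
screen, per-app traffic) for a single user over ``n_days`` calendar days,
following a per-day behavioral regime (workday / weekend / holiday) and an
optional power-saving policy that suspends embedded-sensor sampling while
the screen is off and the device is stationary.  Everything downstream of
raw acquisition can be validated against the returned :class:`GroundTruth`.

All randomness flows from a single :func:`numpy.random.default_rng` seeded
once, so identical inputs produce byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import raw_io
from ._clock import MS_PER_DAY, day_bounds_ms
from .raw_io import SensorStreams, empty_frame

REGIMES = ("workday", "weekend", "holiday")

_M_PER_DEG_LAT = 111_320.0

# Default behavioral regime parameters.  Hourly arrays are indexed by local
# hour 0..23.  Screen intensity is expected session starts per hour; the
# activity profile is the probability that a given second is "high
# activity" (walking-level motion).


def _hourly(night: float, day_vals: Dict[range, float]) -> np.ndarray:
    arr = np.full(24, night)
    for hours, v in day_vals.items():
        for h in hours:
            arr[h] = v
    return arr


def _default_screen_intensity() -> Dict[str, np.ndarray]:
    return {
        "workday": _hourly(0.02, {range(7, 9): 2.0, range(9, 18): 1.0,
                                  range(18, 23): 2.5}),
        "weekend": _hourly(0.02, {range(9, 24): 1.8}),
        "holiday": _hourly(0.05, {range(8, 24): 2.8}),
    }


def _default_activity_prob() -> Dict[str, np.ndarray]:
    return {
        "workday": _hourly(0.0, {range(8, 9): 0.35, range(9, 17): 0.04,
                                 range(17, 18): 0.35, range(18, 22): 0.08}),
        "weekend": _hourly(0.0, {range(9, 22): 0.10}),
        "holiday": _hourly(0.0, {range(9, 22): 0.30}),
    }


def _default_call_rates() -> Dict[str, dict]:
    return {
        "workday": {"incoming": 3.0, "outgoing": 2.0, "missed": 0.3,
                    "mean_incoming_s": 90.0, "mean_outgoing_s": 120.0},
        "weekend": {"incoming": 1.0, "outgoing": 1.0, "missed": 0.2,
                    "mean_incoming_s": 150.0, "mean_outgoing_s": 180.0},
        "holiday": {"incoming": 0.5, "outgoing": 3.0, "missed": 0.2,
                    "mean_incoming_s": 60.0, "mean_outgoing_s": 240.0},
    }


def _default_app_mix() -> Dict[str, Dict[str, float]]:
    return {
        "workday": {"com.whatsapp": 200.0, "com.android.chrome": 400.0,
                    "com.facebook.katana": 100.0},
        "weekend": {"com.whatsapp": 300.0, "com.instagram.android": 500.0,
                    "com.google.android.youtube": 600.0},
        "holiday": {"com.whatsapp": 500.0, "com.tripadvisor.tripadvisor": 400.0,
                    "com.google.android.youtube": 300.0,
                    "com.instagram.android": 700.0},
    }


@dataclass
class UserProfile:
    """Behavioral parameters of the simulated user."""

    home: Tuple[float, float] = (45.0700, 7.6800)
    work: Tuple[float, float] = (45.0880, 7.7000)
    gps_noise_sd: float = 10.0          # metres
    accel_hz: float = 5.0               # nominal embedded-sensor rate
    gps_period_s: float = 60.0          # one fix per minute while sampling
    screen_intensity: Dict[str, np.ndarray] = field(default_factory=_default_screen_intensity)
    screen_mean_session_s: Dict[str, float] = field(
        default_factory=lambda: {"workday": 120.0, "weekend": 180.0, "holiday": 150.0})
    call_rates: Dict[str, dict] = field(default_factory=_default_call_rates)
    app_mix: Dict[str, Dict[str, float]] = field(default_factory=_default_app_mix)
    activity_prob: Dict[str, np.ndarray] = field(default_factory=_default_activity_prob)
    rest_noise_sd: float = 0.05         # m/s^2 around gravity at rest
    motion_amplitude: float = 2.0       # m/s^2 oscillation during activity

    def validate(self) -> None:
        if tuple(self.home) == tuple(self.work):
            raise ValueError("home and work must differ")
        if self.gps_noise_sd < 0 or self.accel_hz <= 0 or self.gps_period_s <= 0:
            raise ValueError("rates and noise must be positive")
        for regime in REGIMES:
            p = np.asarray(self.activity_prob[regime], dtype=float)
            if p.shape != (24,) or (p < 0).any() or (p > 1).any():
                raise ValueError(f"activity_prob[{regime}] must be 24 values in [0,1]")
            lam = np.asarray(self.screen_intensity[regime], dtype=float)
            if lam.shape != (24,) or (lam < 0).any():
                raise ValueError(f"screen_intensity[{regime}] must be 24 rates >= 0")
            for k, v in self.call_rates[regime].items():
                if v < 0:
                    raise ValueError(f"call_rates[{regime}][{k}] must be >= 0")


@dataclass
class PolicyModel:
    """Manufacturer power-saving behavior.

    Subgroup ``A`` devices never interrupt acquisition.  Subgroup ``B``
    devices switch the embedded sensors off once the screen has been off
    for ``screen_off_kill_delay`` seconds while the device is stationary,
    and wake again on the next screen-on (``wake_on_event``) or on
    movement.
    """

    subgroup: str = "A"
    screen_off_kill_delay: float = 300.0
    gps_stationary_suspend: bool = True
    wake_on_event: bool = True

    def validate(self) -> None:
        if self.subgroup not in ("A", "B"):
            raise ValueError("subgroup must be 'A' or 'B'")
        if self.screen_off_kill_delay < 0:
            raise ValueError("screen_off_kill_delay must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream oracles."""

    regime_calendar: Dict[date, str] = field(default_factory=dict)
    true_places: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    policy_gap_intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    high_activity_seconds: Dict[date, int] = field(default_factory=dict)

    def holidays(self) -> List[date]:
        return [d for d, r in sorted(self.regime_calendar.items()) if r == "holiday"]

    def to_dict(self) -> dict:
        return {
            "regime_calendar": {d.isoformat(): r
                                for d, r in sorted(self.regime_calendar.items())},
            "true_places": {k: list(v) for k, v in self.true_places.items()},
            "policy_gap_intervals": {s: [list(g) for g in gs]
                                     for s, gs in self.policy_gap_intervals.items()},
            "high_activity_seconds": {d.isoformat(): n
                                      for d, n in sorted(self.high_activity_seconds.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            regime_calendar={date.fromisoformat(k): v
                             for k, v in d.get("regime_calendar", {}).items()},
            true_places={k: tuple(v) for k, v in d.get("true_places", {}).items()},
            policy_gap_intervals={s: [tuple(g) for g in gs]
                                  for s, gs in d.get("policy_gap_intervals", {}).items()},
            high_activity_seconds={date.fromisoformat(k): int(v)
                                   for k, v in d.get("high_activity_seconds", {}).items()},
        )


def make_regime_calendar(n_days: int, holidays: Sequence[int] = (),
                         start_weekday: int = 0) -> List[str]:
    """Workday Mon-Fri, weekend Sat-Sun, with holiday overrides by day index."""
    hol = set(holidays)
    out = []
    for d in range(n_days):
        if d in hol:
            out.append("holiday")
        elif (start_weekday + d) % 7 >= 5:
            out.append("weekend")
        else:
            out.append("workday")
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _offset_place(origin: Tuple[float, float], dx_m: float,
                  dy_m: float) -> Tuple[float, float]:
    lat, lon = origin
    return (lat + dy_m / _M_PER_DEG_LAT,
            lon + dx_m / (_M_PER_DEG_LAT * math.cos(math.radians(lat))))


def _day_schedule(regime: str, places: Dict[str, Tuple[float, float]],
                  day_index: int) -> List[Tuple[int, int, str, str]]:
    """Blocks (start_s, end_s, from_place, to_place); from == to when parked.

    Transits are short enough that implied speed exceeds the stay-point
    speed filter (> 1.5 m/s), keeping visited places cleanly separable.
    """
    if regime == "workday":
        return [(0, 30600, "home", "home"),
                (30600, 31200, "home", "work"),
                (31200, 63000, "work", "work"),
                (63000, 63600, "work", "home"),
                (63600, 86400, "home", "home")]
    if regime == "weekend":
        return [(0, 86400, "home", "home")]
    away = f"holiday_{day_index}"
    return [(0, 36000, "home", "home"),
            (36000, 37800, "home", away),
            (37800, 72000, away, away),
            (72000, 73800, away, "home"),
            (73800, 86400, "home", "home")]


def _position_at(sec: np.ndarray, schedule, places) -> Tuple[np.ndarray, np.ndarray]:
    """True (lat, lon) for seconds-of-day, linearly interpolating transits."""
    lat = np.empty(len(sec))
    lon = np.empty(len(sec))
    for s0, s1, a, b in schedule:
        m = (sec >= s0) & (sec < s1)
        if not m.any():
            continue
        la0, lo0 = places[a]
        la1, lo1 = places[b]
        if a == b:
            lat[m], lon[m] = la0, lo0
        else:
            f = (sec[m] - s0) / (s1 - s0)
            lat[m] = la0 + f * (la1 - la0)
            lon[m] = lo0 + f * (lo1 - lo0)
    return lat, lon


def generate(profile: UserProfile, policy: PolicyModel, n_days: int, seed: int,
             start_day: date = date(2021, 3, 1),
             regime_calendar: Optional[Sequence[str]] = None,
             holidays: Sequence[int] = (),
             user_id: str = "synthetic-user",
             ) -> Tuple[SensorStreams, GroundTruth]:
    """Simulate ``n_days`` of raw streams.

    Parameters
    ----------
    regime_calendar
        Optional explicit per-day regime labels; default Mon-Fri workdays
        (``start_day`` defaults to a Monday) with ``holidays`` day-index
        overrides.
    """
    profile.validate()
    policy.validate()
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    rng = np.random.default_rng(seed)

    if regime_calendar is None:
        regime_calendar = make_regime_calendar(n_days, holidays,
                                               start_weekday=start_day.weekday())
    if len(regime_calendar) != n_days:
        raise ValueError("regime_calendar length must equal n_days")

    truth = GroundTruth()
    truth.true_places = {"home": tuple(profile.home), "work": tuple(profile.work)}
    streams = SensorStreams(user_id=user_id, day_boundary_tz="UTC")
    if n_days == 0:
        truth.policy_gap_intervals = {"accel": [], "gps": []}
        return streams, truth

    t0_ms, _ = day_bounds_ms(start_day, "UTC")
    n_per_day = int(round(86400 * profile.accel_hz))
    step_ms = 1000.0 / profile.accel_hz
    samples_per_sec = profile.accel_hz

    gps_parts, call_rows, screen_rows, app_rows = [], [], [], []
    # Accel arrays are preallocated for the whole run and filled per day;
    # per-day concatenation of multi-million-row frames is far too slow.
    n_accel = n_days * n_per_day
    acc_t = np.empty(n_accel, dtype="int64")
    acc_ax = np.empty(n_accel)
    acc_ay = np.empty(n_accel)
    acc_az = np.empty(n_accel)
    base_t = np.round(np.arange(n_per_day) * step_ms).astype("int64")
    base_i = np.arange(n_per_day)
    base_sec = (base_i / samples_per_sec).astype("int64")
    hour_of_sec = np.arange(86400) // 3600
    transit_ivs_ms: List[Tuple[int, int]] = []

    # Draw holiday away-places up front so the count of rng calls per day
    # is regime-independent where possible (keeps streams comparable).
    places = dict(truth.true_places)
    for d, regime in enumerate(regime_calendar):
        if regime == "holiday":
            dist = rng.uniform(3000.0, 8000.0)
            bearing = rng.uniform(0.0, 2 * math.pi)
            places[f"holiday_{d}"] = _offset_place(
                profile.home, dist * math.sin(bearing), dist * math.cos(bearing))
    truth.true_places.update({k: v for k, v in places.items() if k.startswith("holiday_")})

    for d, regime in enumerate(regime_calendar):
        day = start_day + timedelta(days=d)
        truth.regime_calendar[day] = regime
        day_ms = t0_ms + d * MS_PER_DAY
        schedule = _day_schedule(regime, places, d)
        for s0, s1, a, b in schedule:
            if a != b:
                transit_ivs_ms.append((day_ms + s0 * 1000, day_ms + s1 * 1000))

        # --- screen sessions ---------------------------------------------
        lam = np.asarray(profile.screen_intensity[regime], dtype=float)
        mean_len = profile.screen_mean_session_s[regime]
        starts = []
        for h in range(24):
            for _ in range(rng.poisson(lam[h])):
                starts.append(h * 3600 + rng.uniform(0, 3600))
        starts.sort()
        sessions = []
        cursor = 0.0
        for s in starts:
            if s < cursor:
                continue
            length = rng.exponential(mean_len)
            e = min(s + length, 86400.0 - 1e-3)
            if e <= s:
                continue
            sessions.append((s, e))
            cursor = e + 1.0
        for s, e in sessions:
            screen_rows.append((day_ms + int(s * 1000), "on"))
            screen_rows.append((day_ms + int(e * 1000), "off"))

        # --- calls --------------------------------------------------------
        rates = profile.call_rates[regime]
        for direction in ("incoming", "outgoing", "missed"):
            n_calls = rng.poisson(rates.get(direction, 0.0))
            for _ in range(n_calls):
                tc = rng.uniform(8 * 3600, 22 * 3600)
                if direction == "missed":
                    dur = 0.0
                else:
                    dur = rng.exponential(rates[f"mean_{direction}_s"])
                call_rows.append((day_ms + int(tc * 1000), direction, round(dur, 1)))

        # --- app traffic (one report per app at session end) -------------
        mix = profile.app_mix[regime]
        for s, e in sessions:
            for app, mean_kb in mix.items():
                if rng.random() < 0.5:
                    kb = rng.exponential(mean_kb)
                    app_rows.append((day_ms + int(e * 1000), app, round(kb, 1)))

        # --- GPS fixes ----------------------------------------------------
        n_fix = int(86400 / profile.gps_period_s)
        fix_sec = np.arange(n_fix) * profile.gps_period_s
        lat, lon = _position_at(fix_sec, schedule, places)
        jitter = rng.normal(0.0, profile.gps_noise_sd, size=(n_fix, 2))
        lat = lat + jitter[:, 0] / _M_PER_DEG_LAT
        lon = lon + jitter[:, 1] / (_M_PER_DEG_LAT * np.cos(np.radians(lat)))
        acc = np.round(np.abs(rng.normal(10.0, 3.0, n_fix)) + 3.0, 1)
        gps_parts.append((day_ms + (fix_sec * 1000).astype("int64"),
                          lat, lon, acc))

        # --- accelerometer ------------------------------------------------
        p_sec = np.asarray(profile.activity_prob[regime], dtype=float)
        high_sec = rng.random(86400) < p_sec[hour_of_sec]
        truth.high_activity_seconds[day] = int(high_sec.sum())

        sl = slice(d * n_per_day, (d + 1) * n_per_day)
        acc_t[sl] = day_ms + base_t
        ax = rng.normal(0.0, 0.03, n_per_day)
        ay = rng.normal(0.0, 0.03, n_per_day)
        az = rng.normal(9.81, profile.rest_noise_sd, n_per_day)
        phase = rng.uniform(0, 2 * math.pi)
        hi = high_sec[base_sec]
        if hi.any():
            ts = base_i[hi] / samples_per_sec
            az[hi] += profile.motion_amplitude * np.sin(2 * math.pi * 1.3 * ts + phase)
        acc_ax[sl] = np.round(ax, 4, out=ax)
        acc_ay[sl] = np.round(ay, 4, out=ay)
        acc_az[sl] = np.round(az, 4, out=az)

    accel = pd.DataFrame({"t": acc_t, "ax": acc_ax, "ay": acc_ay, "az": acc_az},
                         copy=False)
    gps = pd.DataFrame({
        col: np.concatenate([p[i] for p in gps_parts])
        for i, col in enumerate(("t", "lat", "lon", "accuracy"))})
    calls = pd.DataFrame(call_rows, columns=["t", "direction", "duration_s"]) \
        if call_rows else empty_frame("calls")
    screen = pd.DataFrame(screen_rows, columns=["t", "state"]) \
        if screen_rows else empty_frame("screen")
    apps = pd.DataFrame(app_rows, columns=["t", "app_id", "kb"]) \
        if app_rows else empty_frame("apps")
    for df in (calls, screen, apps):
        df.sort_values("t", kind="stable", inplace=True)
        df.reset_index(drop=True, inplace=True)

    span = (t0_ms, t0_ms + n_days * MS_PER_DAY)
    gaps = _policy_gaps(policy, screen, transit_ivs_ms, span)
    truth.policy_gap_intervals = gaps
    accel = _remove_in_intervals(accel, gaps["accel"])
    gps = _remove_in_intervals(gps, gaps["gps"])

    streams = SensorStreams(
        user_id=user_id, accel=accel, gps=gps, calls=calls,
        screen=screen, apps=apps, day_boundary_tz="UTC")
    return streams, truth


def _policy_gaps(policy: PolicyModel, screen: pd.DataFrame,
                 transit_ivs_ms: Sequence[Tuple[int, int]],
                 span: Tuple[int, int]) -> Dict[str, List[Tuple[int, int]]]:
    """Sensor-off intervals induced by the power-saving policy."""
    if policy.subgroup == "A":
        return {"accel": [], "gps": []}
    from .integrity import _complement, _intersect, _screen_off_intervals

    off = _screen_off_intervals(screen, span)
    stationary = _complement(list(transit_ivs_ms), [span])
    delay_ms = int(policy.screen_off_kill_delay * 1000)
    gaps: List[Tuple[int, int]] = []
    if policy.wake_on_event:
        candidates = _intersect(off, stationary)
    else:
        # Without event wake, a kill lasts until the device next moves.
        candidates = []
        for o0, o1 in off:
            for s0, s1 in stationary:
                if s0 <= o0 < s1:
                    candidates.append((o0, s1))
                    break
    for c0, c1 in candidates:
        if c1 - c0 > delay_ms:
            gaps.append((c0 + delay_ms, c1))
    out = {"accel": gaps}
    out["gps"] = gaps if policy.gps_stationary_suspend else []
    return out


def _remove_in_intervals(df: pd.DataFrame,
                         intervals: Sequence[Tuple[int, int]]) -> pd.DataFrame:
    if not intervals or not len(df):
        return df
    t = df["t"].to_numpy()
    drop = np.zeros(len(df), dtype=bool)
    for a, b in intervals:
        lo = np.searchsorted(t, a, side="left")
        hi = np.searchsorted(t, b, side="left")
        drop[lo:hi] = True
    return df[~drop].reset_index(drop=True)


def inject_gap(streams: SensorStreams, sensor: str,
               interval: Tuple[int, int]) -> SensorStreams:
    """Remove every record of ``sensor`` with t in the half-open interval.

    A zero-length interval is a no-op.  The interval must lie within the
    streams' overall time span.
    """
    a, b = interval
    if b < a:
        raise ValueError("reversed interval")
    if a == b:
        return streams
    span = streams.time_span()
    if span is None or b < span[0] or a > span[1]:
        raise ValueError("interval outside the streams' time span")
    return streams.replace(sensor, _remove_in_intervals(streams.get(sensor), [(a, b)]))


def save_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def load_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))
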