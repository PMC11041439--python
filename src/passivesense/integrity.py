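"""Acquisition-gap detection, data-integrity percentage, and power-saving
subgroup classification.

A *segment* is a maximal run of samples in which no two consecutive samples
are more than ``max_interruption`` seconds apart; *gaps* are the complement
of the segments within the observed (or running) span.  The integrity
percentage is ``100 * acquired_hours / running_hours``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .raw_io import SensorStreams, normalize_screen_events

MS_PER_HOUR = 3_600_000.0

#: Default per-sensor maximum inter-sample interruption (seconds).  The
#: 1 s rule applies to the continuously sampled embedded sensors; the GPS
#: registry polls about once a minute, so its threshold is proportionally
#: wider (1.5x the nominal 60 s cadence).
DEFAULT_MAX_INTERRUPTION = {"accel": 1.0, "gps": 90.0}


@dataclass(frozen=True)
class Segment:
    """Maximal uninterrupted sampling run, epoch ms, end >= start."""

    sensor: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("segment end < start")

    @property
    def duration_ms(self) -> int:
        return self.end - self.start


@dataclass
class SensorIntegrity:
    sensor: str
    acquired_hours: float
    running_hours: float
    integrity_pct: float
    segments: List[Segment]
    gaps: List[Tuple[int, int]]


@dataclass
class IntegrityReport:
    per_sensor: Dict[str, SensorIntegrity]
    overall_acquired_hours: float
    overall_running_hours: float
    overall_integrity_pct: float
    running_intervals: List[Tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "overall": {
                "acquired_hours": self.overall_acquired_hours,
                "running_hours": self.overall_running_hours,
                "integrity_pct": self.overall_integrity_pct,
            },
            "per_sensor": {
                s: {
                    "acquired_hours": si.acquired_hours,
                    "running_hours": si.running_hours,
                    "integrity_pct": si.integrity_pct,
                    "n_segments": len(si.segments),
                    "n_gaps": len(si.gaps),
                }
                for s, si in self.per_sensor.items()
            },
        }


def detect_gaps(samples, max_interruption: float = 1.0,
                sensor: str = "") -> List[Segment]:
    """Split a time-sorted stream into maximal segments.

    Parameters
    ----------
    samples
        DataFrame with a ``t`` column, or a 1-D array of epoch-ms times.
    max_interruption
        Largest allowed inter-sample spacing (seconds) inside a segment.

    A single isolated sample yields a zero-duration segment, which keeps
    the segment/gap conservation identity exact.
    """
    t = samples["t"].to_numpy() if isinstance(samples, pd.DataFrame) else np.asarray(samples)
    t = t.astype("int64")
    if len(t) == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be sorted by t")
    limit_ms = max_interruption * 1000.0
    breaks = np.flatnonzero(np.diff(t) > limit_ms)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(t) - 1]))
    return [Segment(sensor, int(t[a]), int(t[b])) for a, b in zip(starts, ends)]


def gaps_between(segments: Sequence[Segment],
                 span: Optional[Tuple[int, int]] = None) -> List[Tuple[int, int]]:
    """Complement of the segments within ``span`` (default: first..last)."""
    if not segments:
        return [tuple(span)] if span is not None else []
    ivs = [(s.start, s.end) for s in segments]
    if span is None:
        span = (ivs[0][0], ivs[-1][1])
    return _complement(ivs, [tuple(span)])


def integrity_percentage(acquired_hours: float, running_hours: float) -> float:
    """``100 * acquired_hours / running_hours``."""
    if running_hours <= 0:
        raise ValueError("running_hours must be > 0 (integrity undefined)")
    if acquired_hours < 0 or acquired_hours > running_hours:
        raise ValueError("require 0 <= acquired_hours <= running_hours")
    return 100.0 * acquired_hours / running_hours


# ---------------------------------------------------------------------------
# Interval arithmetic (all intervals are half-open-ish [start, end], ms)
# ---------------------------------------------------------------------------

def _merge(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals if b >= a)
    out: List[Tuple[int, int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _intersect(xs: Sequence[Tuple[int, int]],
               ys: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out = []
    i = j = 0
    xs, ys = list(xs), list(ys)
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if b > a:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def _complement(xs: Sequence[Tuple[int, int]],
                within: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out = []
    xs = _merge(xs)
    for lo, hi in within:
        cur = lo
        for a, b in xs:
            if b <= cur or a >= hi:
                continue
            if a > cur:
                out.append((cur, min(a, hi)))
            cur = max(cur, b)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
    return out


def _total_ms(intervals: Iterable[Tuple[int, int]]) -> float:
    return float(sum(b - a for a, b in intervals))


def compute_integrity_report(
    streams: SensorStreams,
    running_intervals: Sequence[Tuple[int, int]],
    sensors: Sequence[str] = ("accel", "gps"),
    max_interruption: Optional[Dict[str, float]] = None,
) -> IntegrityReport:
    """Per-sensor and overall integrity over explicit app-running spans.

    ``running_intervals`` are non-overlapping (start, end) epoch-ms spans
    during which acquisition was supposed to be active; for synthetic data
    this is the full generated span.  Overall integrity aggregates sensors
    by duration weighting (total acquired over total running).
    """
    running = _merge(running_intervals)
    if not running or _total_ms(running) <= 0:
        raise ValueError("running_intervals must cover a positive span")
    thresholds = dict(DEFAULT_MAX_INTERRUPTION)
    if max_interruption:
        thresholds.update(max_interruption)

    per_sensor: Dict[str, SensorIntegrity] = {}
    run_h = _total_ms(running) / MS_PER_HOUR
    tot_acq = 0.0
    tot_run = 0.0
    for sensor in sensors:
        df = streams.get(sensor)
        segs = detect_gaps(df, thresholds.get(sensor, 1.0), sensor)
        seg_ivs = _intersect([(s.start, s.end) for s in segs], running)
        gaps = _complement(seg_ivs, running)
        acq_h = _total_ms(seg_ivs) / MS_PER_HOUR
        per_sensor[sensor] = SensorIntegrity(
            sensor=sensor,
            acquired_hours=acq_h,
            running_hours=run_h,
            integrity_pct=integrity_percentage(min(acq_h, run_h), run_h),
            segments=segs,
            gaps=gaps,
        )
        tot_acq += acq_h
        tot_run += run_h
    return IntegrityReport(
        per_sensor=per_sensor,
        overall_acquired_hours=tot_acq,
        overall_running_hours=tot_run,
        overall_integrity_pct=integrity_percentage(min(tot_acq, tot_run), tot_run),
        running_intervals=running,
    )


# ---------------------------------------------------------------------------
# Power-saving subgroup classification
# ---------------------------------------------------------------------------

def _screen_off_intervals(events: pd.DataFrame,
                          span: Tuple[int, int]) -> List[Tuple[int, int]]:
    """Screen-off spans over ``span``.  State before the first event is
    inferred from that event (off before an 'on', on before an 'off')."""
    ev = normalize_screen_events(events)
    lo, hi = span
    if not len(ev):
        return []
    out = []
    t = ev["t"].to_numpy()
    states = ev["state"].to_numpy()
    if states[0] == "on" and t[0] > lo:
        out.append((lo, int(t[0])))
    for i in range(len(ev)):
        if states[i] != "off":
            continue
        start = int(t[i])
        end = int(t[i + 1]) if i + 1 < len(ev) else hi
        out.append((start, end))
    return _intersect(_merge(out), [span])


def classify_policy_subgroup(
    report: IntegrityReport,
    screen_events: pd.DataFrame,
    overlap_threshold: float = 0.8,
    gap_floor: float = 0.05,
    sensor: str = "accel",
) -> str:
    """Classify a device as subgroup ``"A"`` (power-saving policies do not
    interrupt acquisition), ``"B"`` (sensors are switched off while the
    phone is unused), or ``"indeterminate"``.

    Rule: let f be the gap fraction of running time for ``sensor`` and v
    the fraction of total gap time lying inside screen-off intervals.
    A when f <= gap_floor; B when f > gap_floor and v >= overlap_threshold;
    indeterminate otherwise (including when no screen events exist).
    """
    si = report.per_sensor[sensor]
    running = report.running_intervals
    span = (running[0][0], running[-1][1])
    gap_ms = _total_ms(si.gaps)
    run_ms = _total_ms(running)
    gap_frac = gap_ms / run_ms if run_ms else 0.0
    if gap_frac <= gap_floor:
        return "A"
    if not len(screen_events):
        return "indeterminate"
    off = _screen_off_intervals(screen_events, span)
    if not off:
        return "indeterminate"
    overlap_ms = _total_ms(_intersect(si.gaps, off))
    if gap_ms > 0 and overlap_ms / gap_ms >= overlap_threshold:
        return "B"
    return "indeterminate"
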