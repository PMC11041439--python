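import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from passivesense import daily_features as dfeat
from passivesense import synthetic_data as sd

from conftest import DAY0, DAY0_MS, make_accel_df

H_MS = 3_600_000


def _at(hh, mm=0, ss=0, day=0):
    return DAY0_MS + day * 86_400_000 + (hh * 3600 + mm * 60 + ss) * 1000


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

def _calls(rows):
    return pd.DataFrame({
        "t": np.array([r[0] for r in rows], dtype="int64"),
        "direction": [r[1] for r in rows],
        "duration_s": [float(r[2]) for r in rows]})


def test_call_features_direct_formula():
    calls = _calls([(_at(9), "incoming", 60), (_at(10), "incoming", 120),
                    (_at(11), "outgoing", 300)])
    vals, missing = dfeat.call_features(calls, DAY0)
    assert vals["mean_incoming"] == 90
    assert vals["mean_outgoing"] == 300
    assert vals["tot_call_length"] == 480
    assert vals["outgoing_call"] == 1
    assert not missing


def test_no_calls_means_flagged_missing():
    vals, missing = dfeat.call_features(_calls([]), DAY0)
    assert vals["tot_call_length"] == 0
    assert vals["outgoing_call"] == 0
    assert {"mean_incoming", "mean_outgoing"} <= missing


def test_missed_calls_excluded_entirely():
    calls = _calls([(_at(9), "missed", 0)])
    vals, missing = dfeat.call_features(calls, DAY0)
    assert vals["tot_call_length"] == 0
    assert vals["outgoing_call"] == 0
    assert {"mean_incoming", "mean_outgoing"} <= missing


# ---------------------------------------------------------------------------
# Screen sessions / brightness
# ---------------------------------------------------------------------------

def _screen(rows):
    return pd.DataFrame({"t": np.array([r[0] for r in rows], dtype="int64"),
                         "state": [r[1] for r in rows]})


def test_single_session_300s():
    ev = _screen([(_at(10), "on"), (_at(10, 5), "off")])
    sessions = dfeat.screen_sessions(ev, DAY0)
    assert len(sessions) == 1
    assert sessions[0].duration_s == 300
    vals, _ = dfeat.brightness_features(sessions, DAY0)
    assert vals["number_switch_on"] == 1
    assert vals["mean_time_usage"] == 300
    assert vals["b_11"] == 300  # slot 11 covers 10:00-11:00
    assert sum(vals[f"b_{n}"] for n in range(1, 25)) == 300


def test_session_split_at_hour_boundary():
    ev = _screen([(_at(10, 58), "on"), (_at(11, 4), "off")])
    vals, _ = dfeat.brightness_features(dfeat.screen_sessions(ev, DAY0), DAY0)
    assert vals["b_11"] == 120
    assert vals["b_12"] == 240


def test_session_split_at_midnight():
    ev = _screen([(_at(23, 58), "on"), (_at(0, 4, day=1), "off")])
    day2 = DAY0 + timedelta(days=1)
    s1 = dfeat.screen_sessions(ev, DAY0)
    s2 = dfeat.screen_sessions(ev, day2)
    assert [s.duration_s for s in s1] == [120]
    assert [s.duration_s for s in s2] == [240]
    assert s1[0].started_in_day and not s2[0].started_in_day
    v2, _ = dfeat.brightness_features(s2, day2)
    assert v2["number_switch_on"] == 0
    assert v2["b_1"] == 240


def test_day_starting_with_off_event_counts_from_midnight():
    ev = _screen([(_at(0, 10), "off"), (_at(9), "on"), (_at(9, 1), "off")])
    sessions = dfeat.screen_sessions(ev, DAY0)
    assert [s.duration_s for s in sessions] == [600, 60]
    assert not sessions[0].started_in_day


def test_no_sessions_all_zero_and_missing_mean():
    vals, missing = dfeat.brightness_features([], DAY0)
    assert vals["number_switch_on"] == 0
    assert all(vals[f"b_{n}"] == 0 for n in range(1, 25))
    assert "mean_time_usage" in missing


# ---------------------------------------------------------------------------
# Apps
# ---------------------------------------------------------------------------

def _apps(rows):
    return pd.DataFrame({"t": np.array([r[0] for r in rows], dtype="int64"),
                         "app_id": [r[1] for r in rows],
                         "kb": [float(r[2]) for r in rows]})


def test_whatsapp_maps_to_communication():
    vals, _ = dfeat.app_features(_apps([(_at(12), "com.whatsapp", 500)]), DAY0)
    assert vals["tot_kb_communication"] == 500
    assert vals["tot_kb"] == 500
    assert vals["tot_kb_social"] == 0


def test_mixed_categories_and_unknown_app():
    rows = [(_at(9), "com.facebook.katana", 200),
            (_at(10), "com.android.chrome", 300),
            (_at(11), "org.example.game", 100)]
    vals, _ = dfeat.app_features(_apps(rows), DAY0)
    assert vals["tot_kb_social"] == 200
    assert vals["tot_kb_navigation"] == 300
    assert vals["tot_kb_communication"] == 0
    assert vals["tot_kb"] == 600


def test_no_app_records_all_zero():
    vals, missing = dfeat.app_features(_apps([]), DAY0)
    assert vals["tot_kb"] == 0 and not missing


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def test_one_hour_at_rest():
    rng = np.random.default_rng(0)
    t = DAY0_MS + 9 * H_MS + np.arange(0, 3600_000, 200)
    df = make_accel_df(t)
    df["az"] = 9.81 + rng.normal(0, 0.05, len(df))
    vals, missing = dfeat.activity_features(df, DAY0)
    assert vals["s_a_10"] == 0
    assert vals["s_r_10"] == 3600
    assert vals["m_amp_10"] == pytest.approx(9.81, abs=0.01)
    assert "m_amp_1" in missing  # hour without samples
    assert vals["percentage_activity"] == 0


def test_percentage_activity_formula():
    # 1800 high seconds (hour 10), 5400 low seconds (hours 11-12 + half 10)
    t_parts, az_parts = [], []
    base = DAY0_MS + 9 * H_MS
    sec = np.arange(7200)
    t = base + sec * 1000
    az = np.full(7200, 9.81)
    az[:1800] = 9.81 + 2.0  # sustained dynamic amplitude 2 m/s^2
    df = make_accel_df(t)
    df["az"] = az
    vals, _ = dfeat.activity_features(df, DAY0)
    assert vals["s_a_10"] + vals["s_a_11"] == 1800
    total_r = sum(vals[f"s_r_{n}"] for n in range(1, 25))
    assert total_r == 5400
    assert vals["percentage_activity"] == pytest.approx(1800 / 7200)


def test_injected_high_activity_seconds_recovered():
    # needs the nominal 5 Hz rate: per-second classification averages the
    # motion oscillation over 5 samples, so every injected second lands
    # above the threshold
    streams, truth = sd.generate(sd.UserProfile(), sd.PolicyModel("A"),
                                 1, seed=13)
    day = next(iter(truth.high_activity_seconds))
    vals, _ = dfeat.activity_features(streams.accel, day)
    recovered = sum(vals[f"s_a_{n}"] for n in range(1, 25))
    assert recovered == pytest.approx(truth.high_activity_seconds[day], abs=5)


def test_s_a_plus_s_r_equals_sampled_seconds(fast_profile):
    streams, _ = sd.generate(fast_profile, sd.PolicyModel("A"), 1, seed=14)
    vals, _ = dfeat.activity_features(streams.accel, DAY0)
    t = streams.accel["t"].to_numpy()
    sampled_seconds = len(np.unique((t - DAY0_MS) // 1000))
    total = sum(vals[f"s_a_{n}"] + vals[f"s_r_{n}"] for n in range(1, 25))
    assert total == sampled_seconds


# ---------------------------------------------------------------------------
# Assembly invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [1, 2])
def test_featureday_invariants_on_generated_data(fast_profile, seed):
    streams, _ = sd.generate(fast_profile, sd.PolicyModel("A"), 3, seed=seed)
    fds = dfeat.extract_feature_days(streams)
    assert len(fds) == 3
    for fd in fds:
        v = fd.values
        b = [v[f"b_{n}"] for n in range(1, 25)]
        assert all(0 <= x <= 3600 for x in b)
        assert sum(b) <= 86_400
        for n in range(1, 25):
            assert v[f"s_a_{n}"] + v[f"s_r_{n}"] <= 3600
        if "percentage_activity" not in fd.missing:
            assert 0 <= v["percentage_activity"] <= 1
        assert v["tot_kb"] >= (v["tot_kb_social"] + v["tot_kb_communication"]
                               + v["tot_kb_navigation"]) - 1e-9


def test_b_slot_conservation(fast_profile):
    streams, _ = sd.generate(fast_profile, sd.PolicyModel("A"), 2, seed=21)
    for day in [DAY0, DAY0 + timedelta(days=1)]:
        sessions = dfeat.screen_sessions(streams.screen, day)
        vals, _ = dfeat.brightness_features(sessions, day)
        assert sum(vals[f"b_{n}"] for n in range(1, 25)) == pytest.approx(
            sum(s.duration_s for s in sessions), abs=1.0)


def test_feature_days_to_frame_shapes(small_run):
    streams, _ = small_run
    fds = dfeat.extract_feature_days(streams)
    vals, mask = dfeat.feature_days_to_frame(fds)
    assert vals.shape == mask.shape
    assert len(vals) == 7
    assert vals.isna().equals(mask | vals.isna())  # missing entries are NaN
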