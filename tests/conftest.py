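"""Shared fixtures: small synthetic runs and hand-built streams."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from passivesense import synthetic_data as sd

DAY0 = date(2021, 3, 1)          # a Monday
DAY0_MS = 1614556800000          # 2021-03-01T00:00:00Z


@pytest.fixture(scope="session")
def fast_profile():
    """Reduced accel-rate profile: keeps multi-day tests quick; 1 Hz is the
    slowest rate at which consecutive samples still satisfy the 1 s
    no-interruption rule, so integrity semantics are preserved."""
    return sd.UserProfile(accel_hz=1.0)


@pytest.fixture(scope="session")
def small_run(fast_profile):
    """7 policy-A days with one holiday, shared across read-only tests."""
    streams, truth = sd.generate(fast_profile, sd.PolicyModel("A"),
                                 n_days=7, seed=42, holidays=(2,))
    return streams, truth


def make_accel_df(t_ms, value=9.81):
    t_ms = np.asarray(t_ms, dtype="int64")
    return pd.DataFrame({
        "t": t_ms,
        "ax": np.zeros(len(t_ms)),
        "ay": np.zeros(len(t_ms)),
        "az": np.full(len(t_ms), float(value)),
    })


def make_gps_df(rows):
    """rows: iterable of (t_ms, lat, lon)."""
    rows = list(rows)
    return pd.DataFrame({
        "t": np.array([r[0] for r in rows], dtype="int64"),
        "lat": [r[1] for r in rows],
        "lon": [r[2] for r in rows],
        "accuracy": np.full(len(rows), 10.0),
    })
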