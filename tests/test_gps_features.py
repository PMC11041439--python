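import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from passivesense import gps_features as gf
from passivesense import synthetic_data as sd

from conftest import DAY0, DAY0_MS, make_gps_df

LAT0, LON0 = 45.07, 7.68
DLAT_1KM = 1000.0 / 111_320.0


def _minutes(n, start=0):
    return DAY0_MS + (start + np.arange(n) * 60) * 1000


# ---------------------------------------------------------------------------
# haversine / entropy primitives
# ---------------------------------------------------------------------------

def test_haversine_one_degree_latitude():
    d = gf.haversine_m(0.0, 0.0, 1.0, 0.0)
    assert d == pytest.approx(111_195, rel=1e-3)  # pi/180 * 6371 km


def test_entropy_uniform_two_clusters():
    assert gf.dwell_entropy([0.5, 0.5]) == pytest.approx(math.log(2), rel=1e-12)


def test_entropy_80_20():
    assert gf.dwell_entropy([0.8, 0.2]) == pytest.approx(0.500402, abs=1e-5)


def test_entropy_degenerate_zero():
    assert gf.dwell_entropy([1.0]) == 0.0


@settings(max_examples=60, deadline=None)
@given(w=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
def test_entropy_bounds_and_uniform_maximum(w):
    p = np.array(w) / np.sum(w)
    k = len(p)
    h = gf.dwell_entropy(p)
    assert -1e-12 <= h <= math.log(k) + 1e-12
    uniform = np.allclose(p, 1.0 / k)
    if uniform:
        assert h == pytest.approx(math.log(k), rel=1e-9)
    elif k > 1:
        assert h < math.log(k)


# ---------------------------------------------------------------------------
# cluster_fixes
# ---------------------------------------------------------------------------

def _connected_components_oracle(lat, lon, radius):
    """Brute-force single-linkage components over pairwise haversine."""
    n = len(lat)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if gf.haversine_m(lat[i], lon[i], lat[j], lon[j]) <= radius:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def test_two_bouts_1km_apart_two_equal_clusters():
    # 30 fixes at place 1, a fast transition fix, then place 2.  The
    # transition fix and the arrival fix right after it both move faster
    # than the stay-point filter, so place 2 gets 31 raw fixes to end up
    # with 30 stationary ones and a dwell exactly equal to place 1's.
    rows = [(t, LAT0, LON0) for t in _minutes(30)]
    rows += [(DAY0_MS + 1800 * 1000, LAT0 + DLAT_1KM / 2, LON0)]  # transit
    rows += [(t, LAT0 + DLAT_1KM, LON0) for t in _minutes(31, start=1860)]
    fixes = make_gps_df(rows)
    cs = gf.cluster_fixes(fixes, radius=100.0, min_dwell=300.0)
    assert cs.n_clusters == 2
    assert sorted(cs.p) == pytest.approx([0.5, 0.5], abs=1e-9)
    # oracle: stationary fixes only (indices 30 and 31 are in motion)
    stat = fixes.iloc[[i for i in range(len(fixes)) if i not in (30, 31)]]
    n_oracle = _connected_components_oracle(
        stat["lat"].to_numpy(), stat["lon"].to_numpy(), 100.0)
    assert cs.n_clusters == n_oracle


def test_all_fixes_within_10m_single_cluster():
    rng = np.random.default_rng(3)
    jitter = rng.normal(0, 3.0 / 111_320.0, size=(40, 2))
    rows = [(t, LAT0 + jitter[i, 0], LON0 + jitter[i, 1])
            for i, t in enumerate(_minutes(40))]
    cs = gf.cluster_fixes(make_gps_df(rows))
    assert cs.n_clusters == 1
    assert cs.p == pytest.approx([1.0])


def test_single_fix_empty_cluster_set():
    cs = gf.cluster_fixes(make_gps_df([(DAY0_MS, LAT0, LON0)]))
    assert cs.n_clusters == 0


def test_min_dwell_dissolves_brief_visit():
    rows = [(t, LAT0, LON0) for t in _minutes(60)]
    # two-minute stop 1 km away: dwell 120 s < min_dwell 300 s
    rows += [(t, LAT0 + DLAT_1KM, LON0) for t in _minutes(2, start=3900)]
    cs = gf.cluster_fixes(make_gps_df(rows), min_dwell=300.0)
    assert cs.n_clusters == 1


# ---------------------------------------------------------------------------
# identify_home
# ---------------------------------------------------------------------------

def test_single_cluster_is_home():
    rows = [(t, LAT0, LON0) for t in _minutes(30)]
    cs = gf.cluster_fixes(make_gps_df(rows))
    assert gf.identify_home(cs, make_gps_df(rows)) == 0


def test_home_tie_broken_by_total_dwell():
    # Equal night dwell (180 s each), place A has far more daytime dwell.
    dlat_500m = 500.0 / 111_320.0
    rows = [(DAY0_MS + 600_000, LAT0, LON0),
            (DAY0_MS + 660_000, LAT0, LON0),
            (DAY0_MS + 1_200_000, LAT0 + dlat_500m, LON0),
            (DAY0_MS + 1_260_000, LAT0 + dlat_500m, LON0)]
    rows += [(t, LAT0, LON0) for t in _minutes(61, start=36_000)]
    fixes = make_gps_df(rows)
    cs = gf.cluster_fixes(fixes, min_dwell=100.0)
    assert cs.n_clusters == 2
    home = gf.identify_home(cs, fixes)
    c = cs.clusters[home]
    assert gf.haversine_m(c.lat, c.lon, LAT0, LON0) < 50.0


def test_no_night_fixes_falls_back_low_confidence():
    rows = [(t, LAT0, LON0) for t in _minutes(30, start=43_200)]  # midday only
    fixes = make_gps_df(rows)
    cs = gf.cluster_fixes(fixes)
    home = gf.identify_home(cs, fixes)
    assert home == 0
    assert cs.home_low_confidence


def test_synthetic_home_recovered_within_noise(fast_profile):
    streams, truth = sd.generate(fast_profile, sd.PolicyModel("A"), 7, seed=4)
    cs = gf.cluster_fixes(streams.gps)
    home = gf.identify_home(cs, streams.gps)
    c = cs.clusters[home]
    err = gf.haversine_m(c.lat, c.lon, *truth.true_places["home"])
    assert err <= 3 * fast_profile.gps_noise_sd


# ---------------------------------------------------------------------------
# gps_day_features
# ---------------------------------------------------------------------------

def test_all_fixes_one_point():
    rows = [(t, LAT0, LON0) for t in _minutes(120)]
    fixes = make_gps_df(rows)
    cs = gf.cluster_fixes(fixes)
    gf.identify_home(cs, fixes)
    f = gf.gps_day_features(fixes, cs, DAY0)
    assert f.location_variance == 0.0
    assert f.entropy == 0.0
    assert f.time_outside == 0.0
    assert f.number_of_clusters == 1


def test_day_entropy_50_50():
    rows = [(t, LAT0, LON0) for t in _minutes(30)]
    rows += [(DAY0_MS + 1800 * 1000, LAT0 + DLAT_1KM / 2, LON0)]
    rows += [(t, LAT0 + DLAT_1KM, LON0) for t in _minutes(31, start=1860)]
    fixes = make_gps_df(rows)
    cs = gf.cluster_fixes(fixes)
    gf.identify_home(cs, fixes)
    f = gf.gps_day_features(fixes, cs, DAY0)
    assert f.entropy == pytest.approx(math.log(2), rel=1e-9)
    assert f.normalized_entropy == pytest.approx(1.0, rel=1e-9)
    assert len(f.visited_clusters) == 2
    assert f.visited_clusters[0][2] <= f.visited_clusters[1][2]


def test_location_variance_two_fixes():
    fixes = make_gps_df([(DAY0_MS, 0.0, 0.0), (DAY0_MS + 60_000, 0.0, 0.02)])
    cs = gf.cluster_fixes(fixes)
    f = gf.gps_day_features(fixes, cs, DAY0)
    assert f.location_variance == pytest.approx(1.0e-4, rel=1e-12)


def test_location_variance_translation_invariant():
    rng = np.random.default_rng(8)
    lats = LAT0 + rng.normal(0, 1e-3, 50)
    lons = LON0 + rng.normal(0, 1e-3, 50)
    rows1 = [(t, la, lo) for t, la, lo in zip(_minutes(50), lats, lons)]
    rows2 = [(t, la + 0.5, lo - 0.3) for t, la, lo in zip(_minutes(50), lats, lons)]
    f1 = gf.gps_day_features(make_gps_df(rows1),
                             gf.cluster_fixes(make_gps_df(rows1)), DAY0)
    f2 = gf.gps_day_features(make_gps_df(rows2),
                             gf.cluster_fixes(make_gps_df(rows2)), DAY0)
    assert f1.location_variance == pytest.approx(f2.location_variance, rel=1e-9)


def test_no_fixes_that_day_returns_none():
    rows = [(t, LAT0, LON0) for t in _minutes(30)]
    fixes = make_gps_df(rows)
    cs = gf.cluster_fixes(fixes)
    assert gf.gps_day_features(fixes, cs, date(2021, 6, 1)) is None
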