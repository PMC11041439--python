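"""GPS place clustering and daily mobility features.

Fixes are clustered into visited places with a density-based rule on
great-circle distance (fixes within ``radius`` of a cluster's members
join it); clustering runs once over the whole observation window so
cluster identities — and the inferred home — are stable across days.
Per day the module reports the number of places visited, percentage of
time outside home, location variance (variance of longitudes plus
variance of latitudes, degrees^2), location entropy over dwell
proportions (natural log) and its normalized form, and the visited
places ordered by distance from home.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from ._clock import day_bounds_ms, local_hours

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

GPS_FEATURES = ("number_of_clusters", "time_outside", "location_variance",
                "entropy", "normalized_entropy")


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on a 6371 km sphere (vectorized)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((la2 - la1) / 2.0) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def dwell_entropy(p: Sequence[float]) -> float:
    """Shannon entropy (nats) of a dwell-proportion vector; 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return 0.0
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be nonnegative and sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class PlaceCluster:
    lat: float
    lon: float
    member_idx: np.ndarray      # positional indices into the fix frame
    dwell_seconds: float


@dataclass
class PlaceClusterSet:
    """Visited places over the whole observation window.

    ``fix_labels`` assigns each fix (by position) to a cluster index, -1
    for noise or in-transit fixes; ``fix_dwell_s`` is the tracked time
    attributed to each fix.
    """

    clusters: List[PlaceCluster]
    p: np.ndarray                      # dwell proportions over clusters
    fix_labels: np.ndarray
    fix_dwell_s: np.ndarray
    home_index: Optional[int] = None
    home_low_confidence: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def noise_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fix_labels < 0)


def _fix_dwell(t_ms: np.ndarray, fix_cadence_s: float) -> np.ndarray:
    """Seconds of tracked time attributed to each fix: the interval to the
    next fix, capped at twice the nominal cadence."""
    cap = 2.0 * fix_cadence_s
    if len(t_ms) == 0:
        return np.zeros(0)
    dt = np.diff(t_ms) / 1000.0
    dwell = np.minimum(dt, cap)
    return np.concatenate((dwell, [min(fix_cadence_s, cap)]))


def cluster_fixes(fixes: pd.DataFrame, radius: float = 100.0,
                  min_dwell: float = 300.0, max_speed: float = 1.5,
                  fix_cadence_s: float = 60.0) -> PlaceClusterSet:
    """Group GPS fixes into visited places.

    Parameters
    ----------
    radius
        Linkage distance (m): a fix joins a cluster when within ``radius``
        of any of its members.
    min_dwell
        Clusters with less total attributed dwell (s) are dissolved to noise.
    max_speed
        Fixes moving faster than this (m/s, relative to the previous fix)
        are treated as transit and excluded from clustering, but keep
        their dwell attribution for day totals.
    """
    n = len(fixes)
    t = fixes["t"].to_numpy()
    dwell = _fix_dwell(t, fix_cadence_s)
    labels = np.full(n, -1, dtype=int)
    if n < 2:
        return PlaceClusterSet([], np.zeros(0), labels, dwell)

    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    dist_prev = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_prev = np.maximum(np.diff(t) / 1000.0, 1e-9)
    speed = np.concatenate(([0.0], dist_prev / dt_prev))
    stationary = speed <= max_speed

    idx = np.flatnonzero(stationary)
    if len(idx) == 0:
        return PlaceClusterSet([], np.zeros(0), labels, dwell)

    # Pre-aggregate stationary fixes onto a fine grid (radius/4 cells) so
    # DBSCAN runs on a few hundred unique cells instead of every fix; the
    # linkage error this introduces is bounded by one cell diagonal,
    # well below the linkage radius.
    cell_m = radius / 4.0
    dlat = np.degrees(cell_m / EARTH_RADIUS_M)
    lat0 = float(np.mean(lat[idx]))
    dlon = dlat / max(np.cos(np.radians(lat0)), 1e-6)
    cells = np.column_stack((np.round(lat[idx] / dlat).astype(np.int64),
                             np.round(lon[idx] / dlon).astype(np.int64)))
    uniq, inverse = np.unique(cells, axis=0, return_inverse=True)
    centers = np.radians(np.column_stack((uniq[:, 0] * dlat, uniq[:, 1] * dlon)))
    db = DBSCAN(eps=radius / EARTH_RADIUS_M, min_samples=1,
                metric="haversine", algorithm="ball_tree").fit(centers)
    raw = db.labels_[inverse]

    clusters: List[PlaceCluster] = []
    for lab in np.unique(raw[raw >= 0]):
        members = idx[raw == lab]
        total = float(dwell[members].sum())
        if total < min_dwell:
            continue
        w = dwell[members]
        wsum = w.sum() if w.sum() > 0 else 1.0
        clusters.append(PlaceCluster(
            lat=float(np.average(lat[members], weights=w) if w.sum() > 0
                      else lat[members].mean()),
            lon=float(np.average(lon[members], weights=w) if w.sum() > 0
                      else lon[members].mean()),
            member_idx=members,
            dwell_seconds=total,
        ))
    clusters.sort(key=lambda c: -c.dwell_seconds)
    for ci, c in enumerate(clusters):
        labels[c.member_idx] = ci
    tot = sum(c.dwell_seconds for c in clusters)
    p = (np.array([c.dwell_seconds / tot for c in clusters])
         if tot > 0 else np.zeros(len(clusters)))
    return PlaceClusterSet(clusters, p, labels, dwell)


def identify_home(cluster_set: PlaceClusterSet, fixes: pd.DataFrame,
                  tz: str = "UTC", night_hours: Tuple[int, int] = (0, 6)
                  ) -> Optional[int]:
    """Home = cluster with the greatest dwell during local night hours
    (default 00:00-06:00) across all days; ties broken by total dwell.
    With no night-time fixes, falls back to greatest total dwell and sets
    ``home_low_confidence``."""
    if not cluster_set.clusters:
        return None
    hours = local_hours(fixes["t"].to_numpy(), tz)
    night = (hours >= night_hours[0]) & (hours < night_hours[1])
    night_dwell = np.zeros(cluster_set.n_clusters)
    for ci in range(cluster_set.n_clusters):
        m = (cluster_set.fix_labels == ci) & night
        night_dwell[ci] = cluster_set.fix_dwell_s[m].sum()
    totals = np.array([c.dwell_seconds for c in cluster_set.clusters])
    if night_dwell.max() > 0:
        best = night_dwell.max()
        tied = np.flatnonzero(night_dwell == best)
        home = int(tied[np.argmax(totals[tied])])
        cluster_set.home_low_confidence = False
    else:
        home = int(np.argmax(totals))
        cluster_set.home_low_confidence = True
        logger.warning("no night-time fixes; home inferred from total dwell")
    cluster_set.home_index = home
    return home


@dataclass
class GpsDayFeatures:
    number_of_clusters: int
    time_outside: float            # percent
    location_variance: float       # degrees^2
    entropy: float                 # nats
    normalized_entropy: float
    visited_clusters: List[Tuple[float, float, float]]  # (lat, lon, dist_m)


def gps_day_features(fixes: pd.DataFrame, cluster_set: PlaceClusterSet,
                     day: date, tz: str = "UTC") -> Optional[GpsDayFeatures]:
    """Mobility features for one day; None when the day has no fixes.

    Entropy uses that day's dwell proportions across the window-level
    clusters; ``time_outside`` counts transit/noise dwell as outside home.
    """
    start, end = day_bounds_ms(day, tz)
    t = fixes["t"].to_numpy()
    lo_i = int(np.searchsorted(t, start, side="left"))
    hi_i = int(np.searchsorted(t, end, side="left"))
    if hi_i <= lo_i:
        return None
    pos = np.arange(lo_i, hi_i)
    sub = fixes.iloc[lo_i:hi_i]

    lat = sub["lat"].to_numpy()
    lon = sub["lon"].to_numpy()
    # exact zero when all fixes coincide (np.var leaves ~1e-28 residue)
    var_lat = 0.0 if lat.max() == lat.min() else float(np.var(lat))
    var_lon = 0.0 if lon.max() == lon.min() else float(np.var(lon))
    location_variance = var_lat + var_lon

    labels = cluster_set.fix_labels[pos]
    dwell = cluster_set.fix_dwell_s[pos]
    total_dwell = float(dwell.sum())

    day_cluster_dwell = np.zeros(cluster_set.n_clusters)
    for ci in range(cluster_set.n_clusters):
        day_cluster_dwell[ci] = dwell[labels == ci].sum()
    clustered = float(day_cluster_dwell.sum())
    visited = np.flatnonzero(day_cluster_dwell > 0)
    k = len(visited)

    if clustered > 0 and k >= 1:
        q = day_cluster_dwell[visited] / clustered
        entropy = dwell_entropy(q)
    else:
        entropy = 0.0
    normalized = float(entropy / np.log(k)) if k >= 2 else 0.0

    home = cluster_set.home_index
    if home is not None and total_dwell > 0:
        outside = total_dwell - float(day_cluster_dwell[home])
        time_outside = 100.0 * outside / total_dwell
    else:
        time_outside = float("nan")

    visited_list: List[Tuple[float, float, float]] = []
    if home is not None:
        hc = cluster_set.clusters[home]
        for ci in visited:
            c = cluster_set.clusters[ci]
            d = float(haversine_m(np.array([c.lat]), np.array([c.lon]),
                                  np.array([hc.lat]), np.array([hc.lon]))[0])
            visited_list.append((c.lat, c.lon, d))
        visited_list.sort(key=lambda x: x[2])

    return GpsDayFeatures(
        number_of_clusters=k,
        time_outside=time_outside,
        location_variance=location_variance,
        entropy=entropy,
        normalized_entropy=normalized,
        visited_clusters=visited_list,
    )


def gps_day_feature_dict(fixes: pd.DataFrame,
                         cluster_set: Optional[PlaceClusterSet],
                         day: date, tz: str = "UTC"
                         ) -> Tuple[Dict[str, float], FrozenSet[str]]:
    """Scalar GPS features as a (values, missing) pair for FeatureDay."""
    if cluster_set is None:
        return ({f: float("nan") for f in GPS_FEATURES}, frozenset(GPS_FEATURES))
    feats = gps_day_features(fixes, cluster_set, day, tz)
    if feats is None:
        return ({f: float("nan") for f in GPS_FEATURES}, frozenset(GPS_FEATURES))
    values = {
        "number_of_clusters": float(feats.number_of_clusters),
        "time_outside": feats.time_outside,
        "location_variance": feats.location_variance,
        "entropy": feats.entropy,
        "normalized_entropy": feats.normalized_entropy,
    }
    missing = frozenset(f for f, v in values.items() if np.isnan(v))
    return values, missing
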