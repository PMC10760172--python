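"""Occurrence-record preparation: quality filtering, spatial thinning,
group balancing, and target-group background sampling.

The default filter reproduces standard checklist-quality practice for
semi-structured citizen-science bird data: Stationary/Traveling protocols,
duration under 360 minutes, distance travelled under 10 km, start time
between 06:00 and 21:00, at most 10 observers, complete checklists only,
June-July records from 2010-2023, within the north-east Pacific study
extent (175-114 degrees W, 31-62 degrees N).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

#: fixed attribution order for per-criterion rejection counts
REJECTION_ORDER = ("protocol", "duration", "distance", "time", "observers",
                   "complete", "month", "year", "bbox")

REQUIRED_COLUMNS = ("id", "longitude", "latitude", "protocol", "duration_minutes",
                    "effort_distance_km", "start_time", "n_observers", "complete",
                    "date")


@dataclass(frozen=True)
class FilterConfig:
    """Checklist-quality filter thresholds.

    Duration and distance bounds are exclusive, the observer bound is
    inclusive, and the time window is inclusive on both ends. ``bbox`` is
    (lon_min, lon_max, lat_min, lat_max).
    """

    allowed_protocols: frozenset[str] = frozenset({"Stationary", "Traveling"})
    max_duration: float = 360.0
    max_distance: float = 10.0
    time_window: tuple[str, str] = ("06:00", "21:00")
    max_observers: int = 10
    require_complete: bool = True
    months: frozenset[int] = frozenset({6, 7})
    year_range: tuple[int, int] = (2010, 2023)
    bbox: tuple[float, float, float, float] = (-175.0, -114.0, 31.0, 62.0)
    id_blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.bbox[0] > self.bbox[1] or self.bbox[2] > self.bbox[3]:
            raise ValueError("bbox bounds must be ordered (lon_min<=lon_max, lat_min<=lat_max)")
        if not set(self.months) <= set(range(1, 13)):
            raise ValueError("months must be within 1..12")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered")


def _minutes(times: pd.Series) -> pd.Series:
    parts = times.astype(str).str.split(":", expand=True)
    return parts[0].astype(int) * 60 + parts[1].astype(int)


def filter_records(table: pd.DataFrame, config: FilterConfig | None = None
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply every record-quality criterion; return survivors and rejection counts.

    Each dropped row is attributed to its *first* failed criterion in
    REJECTION_ORDER (protocol, duration, distance, time, observers,
    completeness, month, year, bbox); the attribution order affects the
    counts only, never the retained set.
    """
    config = config or FilterConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    dates = pd.to_datetime(table["date"])
    start = _minutes(pd.Series([config.time_window[0]]))[0]
    end = _minutes(pd.Series([config.time_window[1]]))[0]
    t = _minutes(table["start_time"])
    lon, lat = table["longitude"], table["latitude"]

    fail = {
        "protocol": ~table["protocol"].isin(config.allowed_protocols),
        "duration": ~(table["duration_minutes"] < config.max_duration),
        "distance": ~(table["effort_distance_km"] < config.max_distance),
        "time": ~((t >= start) & (t <= end)),
        "observers": ~(table["n_observers"] <= config.max_observers),
        "complete": (~table["complete"].astype(bool)) if config.require_complete
                    else pd.Series(False, index=table.index),
        "month": ~dates.dt.month.isin(config.months),
        "year": ~dates.dt.year.between(*config.year_range),
        "bbox": ~((lon >= config.bbox[0]) & (lon <= config.bbox[1])
                  & (lat >= config.bbox[2]) & (lat <= config.bbox[3])),
    }
    order = list(REJECTION_ORDER)
    if config.id_blacklist:
        # explicit outlier-removal mechanism: attributed last, after bbox
        fail["blacklist"] = table["id"].isin(config.id_blacklist)
        order.append("blacklist")

    rejections: dict[str, int] = {}
    already = pd.Series(False, index=table.index)
    for crit in order:
        first_here = fail[crit] & ~already
        rejections[crit] = int(first_here.sum())
        already = already | fail[crit]
    kept = table.loc[~already].copy()
    return kept, rejections


@dataclass(frozen=True)
class ThinConfig:
    min_distance: float = 0.5  # km
    n_repeats: int = 5
    seed: int = 0
    metric: str = "haversine"  # haversine (lon/lat degrees) | euclidean (planar km)

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.metric not in ("haversine", "euclidean"):
            raise ValueError("metric must be 'haversine' or 'euclidean'")


def pairwise_km(lon: np.ndarray, lat: np.ndarray, metric: str = "haversine") -> np.ndarray:
    """Pairwise distances in km: great-circle for degrees, Euclidean for planar."""
    if metric == "haversine":
        pts = np.radians(np.column_stack([lat, lon]))
        return haversine_distances(pts) * EARTH_RADIUS_KM
    pts = np.column_stack([lon, lat])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _conflict_pairs(lon: np.ndarray, lat: np.ndarray, min_distance: float,
                    metric: str) -> np.ndarray:
    """Index pairs strictly closer than min_distance km.

    Great-circle proximity is resolved through 3-D chord distance, which is
    strictly monotone in arc length, so the chord-radius KD-tree query is
    exact for the great-circle threshold.
    """
    from scipy.spatial import cKDTree

    if metric == "haversine":
        latr, lonr = np.radians(lat), np.radians(lon)
        pts = EARTH_RADIUS_KM * np.column_stack([
            np.cos(latr) * np.cos(lonr), np.cos(latr) * np.sin(lonr), np.sin(latr)])
        radius = 2.0 * EARTH_RADIUS_KM * np.sin(min_distance / (2.0 * EARTH_RADIUS_KM))
    else:
        pts = np.column_stack([lon, lat])
        radius = min_distance
    pairs = cKDTree(pts).query_pairs(radius, output_type="ndarray")
    if len(pairs):  # query_pairs is <= radius; the guarantee is strict
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]
    return pairs


def _thin_once(n: int, neighbors: list[list[int]], rng: np.random.Generator
               ) -> np.ndarray:
    """Greedy max-degree removal on the conflict graph; returns a keep mask."""
    keep = np.ones(n, dtype=bool)
    degree = np.array([len(nb) for nb in neighbors])
    while True:
        max_deg = degree.max(initial=0)
        if max_deg == 0:
            break
        worst = np.where(degree == max_deg)[0]
        victim = worst[rng.integers(len(worst))] if len(worst) > 1 else worst[0]
        keep[victim] = False
        for other in neighbors[victim]:
            if keep[other]:
                degree[other] -= 1
        degree[victim] = 0
    return keep


def thin_spatial(table: pd.DataFrame, config: ThinConfig | None = None) -> pd.DataFrame:
    """Thin records so every retained pair is at least ``min_distance`` km apart.

    Repeats a randomized greedy sweep (remove the point with the most
    close neighbors, random tie-break) ``n_repeats`` times and keeps the
    largest surviving set (ties: first found). The distance guarantee is
    asserted on the result.
    """
    config = config or ThinConfig()
    if len(table) == 0:
        raise ValueError("cannot thin an empty table")
    if len(table) == 1:
        return table.copy()
    lon = table["longitude"].to_numpy(dtype=float)
    lat = table["latitude"].to_numpy(dtype=float)
    pairs = _conflict_pairs(lon, lat, config.min_distance, config.metric)
    if len(pairs) == 0:
        return table.copy()
    neighbors: list[list[int]] = [[] for _ in range(len(table))]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    rng = np.random.default_rng(config.seed)
    best: np.ndarray | None = None
    for _ in range(config.n_repeats):
        keep = _thin_once(len(table), neighbors, rng)
        if best is None or keep.sum() > best.sum():
            best = keep
    kept_idx = np.where(best)[0]
    leftover = _conflict_pairs(lon[kept_idx], lat[kept_idx],
                               config.min_distance, config.metric)
    assert len(leftover) == 0, "thinning postcondition violated"
    return table.iloc[kept_idx].copy()


def balance_groups(tables: dict[str, pd.DataFrame], n_per_group: int = 1500,
                   seed: int = 0) -> dict[str, pd.DataFrame]:
    """Downsample each group to exactly n_per_group rows, uniformly without replacement."""
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for group in sorted(tables):
        df = tables[group]
        if len(df) < n_per_group:
            raise ValueError(
                f"group {group!r} has {len(df)} rows, {n_per_group - len(df)} "
                f"short of the requested {n_per_group}")
        idx = rng.choice(len(df), size=n_per_group, replace=False)
        out[group] = df.iloc[np.sort(idx)].copy()
    return out


def target_group_background(all_species: pd.DataFrame, n: int = 10000,
                            bbox: tuple[float, float, float, float] | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Draw n background points from the all-species occurrence pool.

    Because the pool was collected by the same survey process as the focal
    groups, its spatial density mirrors sampling effort, which is the
    target-group correction for effort bias. Only coordinates are carried.
    """
    pool = all_species
    if bbox is not None:
        lon, lat = pool["longitude"], pool["latitude"]
        inside = (lon >= bbox[0]) & (lon <= bbox[1]) & (lat >= bbox[2]) & (lat <= bbox[3])
        pool = pool.loc[inside]
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} candidate background points for requested {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)][["longitude", "latitude"]].reset_index(drop=True)
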