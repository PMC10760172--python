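"""Checklist filtering, spatial thinning, balancing, background sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nichekit as nk
from nichekit.occurrences import pairwise_km
from conftest import flat_scenario, small_stack


def _metadata_table(n=600, fail=0.15, seed=3):
    stack = small_stack(20, seed=1)
    suit = nk.gaussian_niche_suitability(flat_scenario(), "flat", stack)
    occ = nk.sample_occurrences(suit, n, seed=2)
    return nk.attach_checklist_metadata(occ, fail_fraction=fail, seed=seed)


SYNTH_EXTENT_FILTER = nk.FilterConfig(bbox=(0.0, 20.0, 0.0, 20.0))


class TestFilter:
    def test_retained_ids_equal_generator_clean_ids(self):
        table, ledger = _metadata_table()
        kept, rejections = nk.filter_records(table, SYNTH_EXTENT_FILTER)
        dirty = set(itertools.chain.from_iterable(ledger.values()))
        assert set(kept["id"]) == set(table["id"]) - dirty
        assert sum(rejections.values()) == len(table) - len(kept)

    def test_boundary_duration_exactly_360_rejected(self):
        table, _ = _metadata_table(n=5, fail=0.0)
        table.loc[table.index[0], "duration_minutes"] = 360.0
        table.loc[table.index[1], "duration_minutes"] = 359.9
        kept, rejections = nk.filter_records(table, SYNTH_EXTENT_FILTER)
        assert table["id"].iloc[0] not in set(kept["id"])
        assert table["id"].iloc[1] in set(kept["id"])
        assert rejections["duration"] == 1

    def test_observer_bound_is_inclusive(self):
        table, _ = _metadata_table(n=4, fail=0.0)
        table.loc[table.index[0], "n_observers"] = 10
        table.loc[table.index[1], "n_observers"] = 11
        kept, _ = nk.filter_records(table, SYNTH_EXTENT_FILTER)
        assert table["id"].iloc[0] in set(kept["id"])
        assert table["id"].iloc[1] not in set(kept["id"])

    def test_rejections_attributed_to_first_failed_criterion(self):
        table, _ = _metadata_table(n=3, fail=0.0)
        # violates both protocol (first in order) and duration
        table.loc[table.index[0], "protocol"] = "Incidental"
        table.loc[table.index[0], "duration_minutes"] = 500.0
        _, rejections = nk.filter_records(table, SYNTH_EXTENT_FILTER)
        assert rejections["protocol"] == 1
        assert rejections["duration"] == 0

    def test_idempotent(self):
        table, _ = _metadata_table()
        once, _ = nk.filter_records(table, SYNTH_EXTENT_FILTER)
        twice, rejections = nk.filter_records(once, SYNTH_EXTENT_FILTER)
        assert twice.equals(once)
        assert sum(rejections.values()) == 0

    def test_missing_column_named(self):
        table, _ = _metadata_table(n=5)
        with pytest.raises(ValueError, match="duration_minutes"):
            nk.filter_records(table.drop(columns=["duration_minutes"]),
                              SYNTH_EXTENT_FILTER)

    def test_paper_default_config_values(self):
        cfg = nk.FilterConfig()
        assert cfg.allowed_protocols == {"Stationary", "Traveling"}
        assert cfg.max_duration == 360 and cfg.max_distance == 10
        assert cfg.time_window == ("06:00", "21:00") and cfg.max_observers == 10
        assert cfg.months == {6, 7} and cfg.year_range == (2010, 2023)
        assert cfg.bbox == (-175.0, -114.0, 31.0, 62.0)


def _brute_force_thin_size(lon, lat, min_distance, metric="haversine"):
    """Largest subset with all pairwise distances >= min_distance, by enumeration."""
    n = len(lon)
    dist = pairwise_km(np.asarray(lon), np.asarray(lat), metric)
    best = 0
    for size in range(n, 0, -1):
        for subset in itertools.combinations(range(n), size):
            sub = dist[np.ix_(subset, subset)]
            iu = np.triu_indices(size, 1)
            if size == 1 or (sub[iu] >= min_distance).all():
                return size
    return best


class TestThin:
    def test_three_collinear_points_keep_endpoints(self):
        # ~0.4 km spacing along a meridian; only the endpoints can coexist
        km_per_deg = 111.19
        lats = np.array([0.0, 0.4, 0.8]) / km_per_deg
        table = pd.DataFrame({"id": ["p0", "p1", "p2"], "longitude": 0.0,
                              "latitude": lats})
        thinned = nk.thin_spatial(table, nk.ThinConfig(min_distance=0.5, seed=0))
        assert set(thinned["id"]) == {"p0", "p2"}

    def test_already_sparse_table_unchanged(self):
        table = pd.DataFrame({"id": ["a", "b"], "longitude": [0.0, 1.0],
                              "latitude": [0.0, 1.0]})
        thinned = nk.thin_spatial(table, nk.ThinConfig(min_distance=0.5))
        assert thinned.equals(table)

    def test_distance_guarantee_on_random_clusters(self, rng):
        for trial in range(5):
            center_lon = rng.uniform(-130, -120)
            center_lat = rng.uniform(35, 55)
            n = 60
            table = pd.DataFrame({
                "id": [f"r{trial}_{i}" for i in range(n)],
                "longitude": center_lon + rng.normal(0, 0.01, n),
                "latitude": center_lat + rng.normal(0, 0.01, n),
            })
            thinned = nk.thin_spatial(table, nk.ThinConfig(min_distance=0.5, seed=trial))
            d = pairwise_km(thinned["longitude"].to_numpy(),
                            thinned["latitude"].to_numpy(), "haversine")
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 0.5

    def test_matches_brute_force_optimum_on_small_instances(self, rng):
        for trial in range(8):
            n = int(rng.integers(5, 13))
            lon = -125 + rng.normal(0, 0.008, n)
            lat = 45 + rng.normal(0, 0.008, n)
            table = pd.DataFrame({"id": [str(i) for i in range(n)],
                                  "longitude": lon, "latitude": lat})
            thinned = nk.thin_spatial(table, nk.ThinConfig(
                min_distance=0.5, n_repeats=20, seed=trial))
            assert len(thinned) == _brute_force_thin_size(lon, lat, 0.5)

    def test_single_point_returned_unchanged(self):
        table = pd.DataFrame({"id": ["x"], "longitude": [0.0], "latitude": [0.0]})
        assert nk.thin_spatial(table).equals(table)


class TestBalance:
    def test_exact_counts_and_subset(self, rng):
        tables = {
            g: pd.DataFrame({"id": [f"{g}{i}" for i in range(n)],
                             "longitude": rng.uniform(0, 1, n),
                             "latitude": rng.uniform(0, 1, n)})
            for g, n in [("west", 400), ("glau", 350), ("hyb", 300)]
        }
        balanced = nk.balance_groups(tables, 250, seed=1)
        for g, df in balanced.items():
            assert len(df) == 250
            assert set(df["id"]) <= set(tables[g]["id"])

    def test_exact_size_group_unchanged_up_to_order(self):
        df = pd.DataFrame({"id": list("abcde"), "longitude": range(5),
                           "latitude": range(5)})
        out = nk.balance_groups({"g": df}, 5, seed=0)["g"]
        assert set(out["id"]) == set(df["id"])

    def test_shortfall_names_group(self):
        df = pd.DataFrame({"id": ["a"], "longitude": [0], "latitude": [0]})
        with pytest.raises(ValueError, match="hyb.*9 short|hyb"):
            nk.balance_groups({"hyb": df}, 10, seed=0)

    def test_deterministic(self, rng):
        df = pd.DataFrame({"id": [str(i) for i in range(100)],
                           "longitude": rng.uniform(0, 1, 100),
                           "latitude": rng.uniform(0, 1, 100)})
        a = nk.balance_groups({"g": df}, 40, seed=5)["g"]
        b = nk.balance_groups({"g": df}, 40, seed=5)["g"]
        assert a.equals(b)


class TestBackground:
    def test_uniform_pool_gives_uniform_background(self, rng):
        n = 8000
        pool = pd.DataFrame({"id": [str(i) for i in range(n)],
                             "longitude": rng.uniform(0, 1, n),
                             "latitude": rng.uniform(0, 1, n)})
        bg = nk.target_group_background(pool, 2000, seed=2)
        assert list(bg.columns) == ["longitude", "latitude"]
        qx = (bg["longitude"] > 0.5).astype(int)
        qy = (bg["latitude"] > 0.5).astype(int)
        counts = pd.crosstab(qx, qy).to_numpy().ravel()
        assert stats.chisquare(counts).pvalue > 0.001

    def test_insufficient_candidates_rejected(self):
        pool = pd.DataFrame({"id": ["a"], "longitude": [0.0], "latitude": [0.0]})
        with pytest.raises(ValueError, match="candidate background"):
            nk.target_group_background(pool, 5, seed=0)

    def test_bbox_restriction_and_determinism(self, rng):
        pool = pd.DataFrame({"id": [str(i) for i in range(1000)],
                             "longitude": rng.uniform(0, 2, 1000),
                             "latitude": rng.uniform(0, 2, 1000)})
        a = nk.target_group_background(pool, 100, bbox=(0, 1, 0, 1), seed=3)
        b = nk.target_group_background(pool, 100, bbox=(0, 1, 0, 1), seed=3)
        assert a.equals(b)
        assert a["longitude"].between(0, 1).all()
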