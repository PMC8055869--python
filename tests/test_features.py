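"""Tests of geodesic, fire, buffer, temporal and join feature builders."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmstack import features as F
from pmstack.geo import Grid, haversine_km
from pmstack.synthetic import WorldConfig, generate_world

from . import _oracles as O
from .conftest import SMALL_CONFIG


class TestHaversine:
    def test_identity_is_zero(self):
        assert haversine_km(-118.0, 39.0, -118.0, 39.0) == 0.0

    def test_antipodal_closed_form(self):
        assert haversine_km(0.0, 0.0, 180.0, 0.0) == pytest.approx(
            np.pi * 6371.0088, abs=1e-6
        )

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-85, 85, 2)
            assert haversine_km(lon1, lat1, lon2, lat2) == pytest.approx(
                O.slc_distance_km(lon1, lat1, lon2, lat2), abs=1e-6
            )

    def test_symmetry(self):
        assert haversine_km(-120, 36, -115, 42) == haversine_km(-115, 42, -120, 36)

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(ValueError, match="lat"):
            haversine_km(0.0, 95.0, 0.0, 0.0)


def _km_east(lon, lat, km):
    return lon + km / (111.32 * np.cos(np.radians(lat)))


class TestFireProximity:
    def test_no_fires_in_window_all_zero(self):
        fires = pd.DataFrame(
            {"lon": [_km_east(-118, 39, 600)], "lat": [39.0],
             "date": [pd.Timestamp("2013-01-05")], "size": [10.0]}
        )
        out = F.fire_proximity_features(-118.0, 39.0, "2013-01-05", fires)
        assert all(v == 0.0 for v in out.values())

    def test_single_same_day_fire(self):
        fires = pd.DataFrame(
            {"lon": [_km_east(-118, 39, 10)], "lat": [39.0],
             "date": [pd.Timestamp("2013-01-05")], "size": [10.0]}
        )
        out = F.fire_proximity_features(-118.0, 39.0, "2013-01-05", fires)
        assert out["fire_idw_lag0"] > 0
        assert all(out[f"fire_idw_lag{l}"] == 0.0 for l in range(1, 8))
        assert out["fire_within_500km_week"] == 1.0

    def test_two_fires_weighted_mean_closed_form(self):
        fires = pd.DataFrame(
            {
                "lon": [_km_east(-118, 39, 10), _km_east(-118, 39, 40)],
                "lat": [39.0, 39.0],
                "date": pd.Timestamp("2013-01-05"),
                "size": 1.0,
            }
        )
        out = F.fire_proximity_features(-118.0, 39.0, "2013-01-05", fires)
        # counts per cumulative radius: (1, 2, 2, 2)
        w = np.array([1 / 25, 1 / 50, 1 / 100, 1 / 500])
        expected = (np.array([1, 2, 2, 2]) * w).sum() / w.sum()
        assert out["fire_idw_lag0"] == pytest.approx(expected, abs=1e-12)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(11)
        dates = pd.date_range("2013-06-01", periods=15)
        fires = pd.DataFrame(
            {
                "lon": rng.uniform(-121, -114, 40),
                "lat": rng.uniform(36, 42, 40),
                "date": rng.choice(dates, 40),
                "size": rng.uniform(1, 30, 40),
            }
        )
        for _ in range(6):
            lon, lat = rng.uniform(-121, -114), rng.uniform(36, 42)
            date = rng.choice(dates[8:])
            got = F.fire_proximity_features(lon, lat, date, fires)
            want = O.fire_idw_brute(lon, lat, date, fires)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-9), k

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("2013-01-01", periods=20)
        fires = pd.DataFrame(
            {
                "lon": rng.uniform(-121, -114, 30),
                "lat": rng.uniform(36, 42, 30),
                "date": rng.choice(dates, 30),
                "size": 1.0,
            }
        )
        pts = rng.uniform([-121, 36], [-114, 42], (4, 2))
        idw, ind = F.fire_feature_arrays(pts[:, 0], pts[:, 1], dates, fires)
        for i in range(4):
            for d in (0, 7, 19):
                sc = F.fire_proximity_features(pts[i, 0], pts[i, 1], dates[d], fires)
                for l in range(8):
                    assert idw[i, d, l] == pytest.approx(sc[f"fire_idw_lag{l}"], abs=1e-12)
                assert ind[i, d] == sc["fire_within_500km_week"]

    def test_distant_fires_give_exact_zero(self):
        fires = pd.DataFrame(
            {"lon": [-100.0], "lat": [30.0], "date": [pd.Timestamp("2013-01-05")], "size": [99.0]}
        )
        out = F.fire_proximity_features(-121.0, 42.0, "2013-01-05", fires)
        assert all(v == 0.0 for v in out.values())


class TestBufferFraction:
    def _grid(self, codes):
        n = codes.shape[0]
        lon = np.linspace(-118.3, -117.7, n)
        lat = np.linspace(38.7, 39.3, n)
        return Grid(lon, lat, codes)

    def test_all_urban_is_one(self):
        g = self._grid(np.full((9, 9), 23))
        for r in (1.0, 5.0, 10.0):
            assert F.buffer_fraction(g, -118.0, 39.0, r) == 1.0

    def test_no_urban_is_zero(self):
        g = self._grid(np.full((9, 9), 52))
        assert F.buffer_fraction(g, -118.0, 39.0, 10.0) == 0.0

    def test_half_plane_split(self):
        codes = np.full((21, 21), 52)
        codes[:, 11:] = 23  # urban east of the point's meridian
        g = self._grid(codes)
        got = F.buffer_fraction(g, -118.0, 39.0, 20.0)
        want = O.buffer_fraction_brute(g, -118.0, 39.0, 20.0, (22, 23, 24))
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.5, abs=0.1)

    def test_subcell_radius_uses_nearest_cell(self):
        codes = np.full((5, 5), 52)
        codes[2, 2] = 23
        lon = np.linspace(-119, -117, 5)
        lat = np.linspace(38, 40, 5)
        g = Grid(lon, lat, codes)
        assert F.buffer_fraction(g, -118.0, 39.0, 0.5) == 1.0  # nearest cell is urban

    def test_random_points_match_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        codes = rng.choice([22, 23, 24, 41, 52], size=(12, 12))
        g = self._grid(codes)
        for _ in range(5):
            lon, lat = rng.uniform(-118.25, -117.75), rng.uniform(38.75, 39.25)
            r = rng.uniform(3, 30)
            assert F.buffer_fraction(g, lon, lat, r) == pytest.approx(
                O.buffer_fraction_brute(g, lon, lat, r, (22, 23, 24)), abs=1e-12
            )


class TestRoadLength:
    def _straight_road(self, length_km=10.0, lat=39.0):
        n = 41
        s = np.linspace(-length_km / 2, length_km / 2, n)
        return pd.DataFrame(
            {
                "road_id": "R1",
                "road_class": "arterial",
                "seq": np.arange(n),
                "lon": _km_east(-118.0, lat, s),
                "lat": lat,
            }
        )

    def test_no_roads_zero(self):
        empty = pd.DataFrame(columns=["road_id", "road_class", "seq", "lon", "lat"])
        assert F.buffer_road_length(empty, -118.0, 39.0, 500) == 0.0

    def test_chord_through_centre(self):
        roads = self._straight_road()
        for r in (250, 500, 1000):
            got = F.buffer_road_length(roads, -118.0, 39.0, r)
            assert got == pytest.approx(2 * r / 1000.0, rel=0.06)

    def test_excluded_class_ignored(self):
        roads = self._straight_road()
        roads["road_class"] = "local"
        assert F.buffer_road_length(roads, -118.0, 39.0, 1000) == 0.0

    def test_matches_one_metre_densification_oracle(self, small_world):
        roads = small_world.roads
        rng = np.random.default_rng(9)
        mons = small_world.monitors.iloc[:4]
        for row in mons.itertuples():
            r = float(rng.choice([250, 500, 1000]))
            got = F.buffer_road_length(roads, row.lon, row.lat, r)
            want = O.road_length_brute(roads, row.lon, row.lat, r)
            assert got == pytest.approx(want, rel=0.01, abs=1e-6)


class TestTemporalHarmonics:
    def test_january_first_is_phase_origin(self):
        h = F.temporal_harmonics(["2013-01-01"])
        assert h.loc[0, "cos_doy"] == 1.0
        assert h.loc[0, "cos_month"] == 1.0

    def test_year_boundary_alignment(self):
        h = F.temporal_harmonics(["2013-12-31", "2014-01-01"])
        assert abs(h.loc[0, "cos_doy"] - h.loc[1, "cos_doy"]) < 0.01

    def test_midyear_value(self):
        h = F.temporal_harmonics(["2013-07-02"])  # day 183 of a non-leap year
        assert h.loc[0, "cos_doy"] == pytest.approx(
            np.cos(2 * np.pi * 182 / 365.25), abs=1e-12
        )
        assert h.loc[0, "cos_doy"] == pytest.approx(-1.0, abs=1e-3)

    def test_monday_origin_for_day_of_week(self):
        h = F.temporal_harmonics(["2013-01-07"])  # a Monday
        assert h.loc[0, "cos_dow"] == 1.0

    @given(st.integers(0, 3000))
    @settings(max_examples=30, deadline=None)
    def test_phase_periodicity(self, day_offset):
        d = pd.Timestamp("2010-01-01") + pd.Timedelta(days=day_offset)
        doy = float(d.dayofyear)
        phase = np.cos(2 * np.pi * (doy - 1) / 365.25)
        phase_shifted = np.cos(2 * np.pi * (doy - 1 + 365.25) / 365.25)
        assert phase == pytest.approx(phase_shifted, abs=1e-9)
        got = F.temporal_harmonics([d]).loc[0, "cos_doy"]
        assert got == pytest.approx(phase, abs=1e-12)


class TestSpatiotemporalBasis:
    def test_period_dummies(self):
        b = F.spatiotemporal_basis(["WA"], [-120.0], [47.0], ["2014-06-01"])
        assert b.loc[0, "period_2013_2016"] == 1.0
        assert b.loc[0, "period_2008_2012"] == 0.0
        assert b.loc[0, "period_2017_2018"] == 0.0

    def test_washington_is_northwest(self):
        b = F.spatiotemporal_basis(["WA"], [-120.0], [47.0], ["2014-06-01"])
        assert b.loc[0, "region_northwest"] == 1.0

    def test_one_hot_groups_sum_to_one_and_interaction_is_product(self):
        states = ["WA", "CA", "UT", "MT", "NM"]
        dates = ["2009-03-01", "2013-07-04", "2016-12-25", "2017-01-01", "2018-10-31"]
        b = F.spatiotemporal_basis(states, [-120] * 5, [40] * 5, dates)
        for group in ("period_", "season_", "region_", "state_"):
            cols = [c for c in b.columns if c.startswith(group) and "x_region" not in c]
            np.testing.assert_allclose(b[cols].sum(axis=1), 1.0)
        inter = [c for c in b.columns if "_x_region_" in c]
        np.testing.assert_allclose(b[inter].sum(axis=1), 1.0)
        for c in inter:
            p, r = c.split("_x_region_")
            np.testing.assert_allclose(b[c], b[p] * b[f"region_{r}"])

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError, match="XX"):
            F.spatiotemporal_basis(["XX"], [-120.0], [40.0], ["2014-01-01"])


class TestDailyMetMeans:
    def test_constant_records(self):
        rec = pd.DataFrame({"pbl": [700.0] * 4, "hour": [0, 6, 12, 18]})
        assert F.daily_met_means(rec)["pbl"] == 700.0

    def test_arithmetic_mean(self):
        rec = pd.DataFrame({"temp": [1.0, 2.0, 3.0, 4.0]})
        assert F.daily_met_means(rec)["temp"] == 2.5

    def test_partial_records_use_available(self):
        rec = pd.DataFrame({"temp": [10.0, 20.0]})
        assert F.daily_met_means(rec)["temp"] == 15.0

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(2)
        panel = pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(10), 4),
                "hour": np.tile([0, 6, 12, 18], 10),
                "pbl": rng.uniform(100, 2000, 40),
                "temp": rng.normal(10, 8, 40),
            }
        )
        oracle = panel.groupby("cell_id")[["pbl", "temp"]].mean()
        for cid, grp in panel.groupby("cell_id"):
            got = F.daily_met_means(grp)
            assert got["pbl"] == pytest.approx(oracle.loc[cid, "pbl"], abs=1e-12)
            assert got["temp"] == pytest.approx(oracle.loc[cid, "temp"], abs=1e-12)


class TestNearestJoin:
    def _source(self):
        return pd.DataFrame(
            {
                "lon": [-118.0, -118.0, -117.0],
                "lat": [38.0, 40.0, 39.0],
                "date": pd.Timestamp("2013-01-01"),
                "value": [1.0, 2.0, 3.0],
            }
        )

    def test_target_on_source_node(self):
        t = pd.DataFrame({"lon": [-117.0], "lat": [39.0], "date": [pd.Timestamp("2013-01-01")]})
        r = F.nearest_join(t, self._source())
        assert r.loc[0, "value"] == 3.0 and r.loc[0, "distance_km"] == 0.0

    def test_equidistant_tie_takes_lowest_index(self):
        src = pd.DataFrame(
            {
                "lon": [-118.0, -118.0, -110.0],
                "lat": [38.0, 40.0, 39.0],
                "date": pd.Timestamp("2013-01-01"),
                "value": [1.0, 2.0, 3.0],
            }
        )
        t = pd.DataFrame({"lon": [-118.0], "lat": [39.0], "date": [pd.Timestamp("2013-01-01")]})
        r = F.nearest_join(t, src)
        assert r.loc[0, "source_index"] == 0 and r.loc[0, "value"] == 1.0

    def test_missing_date_propagates_flag(self):
        t = pd.DataFrame({"lon": [-117.0], "lat": [39.0], "date": [pd.Timestamp("2013-01-02")]})
        r = F.nearest_join(t, self._source())
        assert np.isnan(r.loc[0, "value"]) and r.loc[0, "missing"] == 1

    def test_empty_source_rejected(self):
        t = pd.DataFrame({"lon": [-117.0], "lat": [39.0], "date": [pd.Timestamp("2013-01-01")]})
        with pytest.raises(ValueError):
            F.nearest_join(t, self._source().iloc[0:0])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        n_src, n_tgt = 30, 200
        dates = pd.date_range("2013-01-01", periods=5)
        src = pd.DataFrame(
            {
                "lon": np.repeat(rng.uniform(-121, -114, n_src), 5),
                "lat": np.repeat(rng.uniform(36, 42, n_src), 5),
                "date": np.tile(dates, n_src),
                "value": rng.normal(size=n_src * 5),
            }
        )
        tgt = pd.DataFrame(
            {
                "lon": rng.uniform(-121, -114, n_tgt),
                "lat": rng.uniform(36, 42, n_tgt),
                "date": rng.choice(dates, n_tgt),
            }
        )
        r = F.nearest_join(tgt, src)
        s_lon = src["lon"].to_numpy()[::5]
        s_lat = src["lat"].to_numpy()[::5]
        idx, dist = O.nearest_scan(tgt["lon"], tgt["lat"], s_lon, s_lat)
        np.testing.assert_array_equal(r["source_index"].to_numpy(), idx)
        np.testing.assert_allclose(r["distance_km"].to_numpy(), dist, atol=1e-6)


class TestAssembleFeatures:
    def test_row_count_and_order_preserved(self, small_features, qc_obs):
        assert len(small_features) == len(qc_obs)
        assert (small_features["location_id"].to_numpy() == qc_obs["monitor_id"].to_numpy()).all()

    def test_ctm_toggle(self, qc_obs, small_world):
        keys = qc_obs.rename(columns={"monitor_id": "location_id"}).head(50)[
            ["location_id", "lon", "lat", "state", "date"]
        ]
        without = F.assemble_features(keys, small_world, include_ctm=False)
        assert "ctm_pm25" not in without.columns
        with_ctm = F.assemble_features(keys, small_world, include_ctm=True)
        assert "ctm_pm25" in with_ctm.columns
        shared = [c for c in without.columns if c != "date"]
        pd.testing.assert_frame_equal(without[shared], with_ctm[shared])

    def test_zero_fire_world_all_fire_columns_zero(self, qc_obs):
        cfg = SMALL_CONFIG.to_dict()
        cfg.update(fire_rate=0.0, n_mobile_fire_monitors=0)
        quiet = generate_world(WorldConfig.from_dict(cfg))
        keys = qc_obs.rename(columns={"monitor_id": "location_id"}).head(40)[
            ["location_id", "lon", "lat", "state", "date"]
        ]
        feats = F.assemble_features(keys, quiet)
        fire_cols = [c for c in feats.columns if c.startswith("fire_")]
        assert (feats[fire_cols].to_numpy() == 0).all()

    def test_date_outside_span_rejected(self, qc_obs, small_world):
        keys = qc_obs.rename(columns={"monitor_id": "location_id"}).head(1)[
            ["location_id", "lon", "lat", "state", "date"]
        ].copy()
        keys["date"] = pd.Timestamp("2030-01-01")
        with pytest.raises(ValueError, match="2030"):
            F.assemble_features(keys, small_world)

    def test_dummy_groups_complete(self, small_features):
        for group in ("season_", "region_", "state_"):
            cols = [c for c in small_features.columns
                    if c.startswith(group) and "x_region" not in c]
            np.testing.assert_allclose(small_features[cols].sum(axis=1), 1.0)

    def test_missing_flags_mark_nan_cells(self, small_features):
        assert (
            small_features["miss_aod"].to_numpy()
            == np.isnan(small_features["aod"].to_numpy()).astype(int)
        ).all()
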