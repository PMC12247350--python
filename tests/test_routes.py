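"""Track interpolation, mean-route averaging and band statistics."""

import numpy as np
import pandas as pd
import pytest

from trackfidelity import geo
from trackfidelity.clustering import ClusterParams, st_dbscan
from trackfidelity.routes import (InterpolatedTrack, band_entry_dates,
                                  band_lon_deviation, collapse_to_centers,
                                  interpolate_track, mean_route, resample_route)
from .conftest import make_track


def meridian_track(lon, lat_hi=60.0, lat_lo=20.0, n=200, bird="b1", year=2020,
                   direction="south"):
    lats = np.linspace(lat_hi, lat_lo, n)
    pos = pd.DataFrame({
        "timestamp": pd.date_range("2020-08-01", periods=n, freq="15min", tz="UTC"),
        "lon": lon, "lat": lats, "valid": True})
    return InterpolatedTrack(bird_id=bird, cycle_year=year, direction=direction,
                             positions=pos)


# ------------------------------------------------------------- interpolation

def test_linear_midpoint_between_two_fixes():
    tr = make_track([0.0, 10.0], [0.0, 0.0], [0, 10])
    it = interpolate_track(tr, dt_min=300, mode="linear")   # grid at 0, 5, 10 h
    mid = it.positions.iloc[1]
    assert mid["lon"] == pytest.approx(5.0, abs=1e-6)
    assert mid["lat"] == pytest.approx(0.0, abs=1e-6)


def test_stationary_fixes_stay_put_in_both_modes():
    tr = make_track([3.0] * 20, [40.0] * 20, np.arange(20) * 2.0)
    for mode in ("linear", "kalman"):
        it = interpolate_track(tr, dt_min=15, mode=mode)
        assert np.allclose(it.positions["lon"], 3.0, atol=0.02)
        assert np.allclose(it.positions["lat"], 40.0, atol=0.02)


def test_kalman_passes_near_fixes_with_small_obs_noise():
    rng = np.random.default_rng(0)
    n = 40
    lats = np.linspace(50, 45, n)
    tr = make_track(np.zeros(n), lats, np.arange(n) * 3.0, lc="3")
    it = interpolate_track(tr, dt_min=180, mode="kalman",
                           obs_sd_by_class={"3": 1.0})
    # grid coincides with every other fix time
    obs = tr.iloc[::1]
    interp = it.positions
    merged = interp.merge(tr, on="timestamp", suffixes=("_i", "_o"))
    d = geo.geodesic_m(merged["lon_i"], merged["lat_i"],
                       merged["lon_o"], merged["lat_o"])
    assert np.median(d) < 200.0


def test_transmission_gap_flagged_invalid():
    hours = list(np.arange(10) * 6) + list(np.arange(10) * 6 + 132)  # 3.5-day gap
    tr = make_track(np.zeros(20), np.linspace(50, 49, 20), hours)
    it = interpolate_track(tr, dt_min=15, mode="linear")
    pos = it.positions
    gap_mid = (pos["timestamp"] > tr["timestamp"].iloc[9] + pd.Timedelta("13h")) & \
              (pos["timestamp"] < tr["timestamp"].iloc[10] - pd.Timedelta("13h"))
    assert (~pos.loc[gap_mid, "valid"]).all()
    assert pos["valid"].iloc[0] and pos["valid"].iloc[-1]


def test_validity_depends_only_on_timestamps():
    hours = np.concatenate([np.arange(10) * 6, np.arange(10) * 6 + 132])
    tr1 = make_track(np.zeros(20), np.linspace(50, 49, 20), hours)
    tr2 = make_track(np.ones(20) * 7, np.linspace(10, 9, 20), hours)
    v1 = interpolate_track(tr1, mode="linear").positions["valid"]
    v2 = interpolate_track(tr2, mode="linear").positions["valid"]
    assert v1.equals(v2)


def test_too_few_fixes_returns_none():
    tr = make_track([0.0], [0.0], [0])
    assert interpolate_track(tr) is None


def test_collapse_to_centers_replaces_only_cluster_members():
    hours = list(np.arange(6) * 6) + [100, 106]
    lons = [0.0, 0.001, -0.001, 0.0005, 0.0, 0.001, 5.0, 9.0]
    lats = [30.0, 30.001, 30.0, 30.0, 29.999, 30.0, 33.0, 36.0]
    tr = make_track(lons, lats, hours)
    clusters, noise = st_dbscan(tr, ClusterParams(3, 4000, 10))
    assert len(clusters) == 1 and len(noise) == 2
    out = collapse_to_centers(tr, clusters)
    assert out["lon"].iloc[:6].nunique() == 1      # members share the centre
    assert out["lon"].iloc[6] == 5.0               # noise untouched
    assert (out["timestamp"] == tr["timestamp"]).all()


# ---------------------------------------------------------------- mean route

def test_mean_route_single_track_identity():
    t = meridian_track(-100.0)
    mr = mean_route([t], n=500)
    assert mr.points.shape == (500, 2)
    assert mr.objective_km == 0.0
    ref = resample_route(t.positions["lon"].to_numpy(),
                         t.positions["lat"].to_numpy(), 500)
    np.testing.assert_allclose(mr.points, ref, atol=1e-9)


def test_mean_route_two_meridians_gives_midline():
    t1 = meridian_track(-101.0)
    t2 = meridian_track(-99.0)
    mr = mean_route([t1, t2], n=500)
    mid_dev_km = geo.geodesic_km(mr.points[:, 0], mr.points[:, 1],
                                 np.full(500, -100.0), mr.points[:, 1])
    assert np.max(mid_dev_km) < 1.0
    assert all(b <= a + 1e-9 for a, b in zip(mr.objective_history,
                                             mr.objective_history[1:]))


def test_mean_route_longitude_translation_equivariance():
    tracks = [meridian_track(-101.0), meridian_track(-98.5)]
    mr = mean_route(tracks, n=200)
    shifted = [meridian_track(-101.0 + 5.0), meridian_track(-98.5 + 5.0)]
    mr2 = mean_route(shifted, n=200)
    np.testing.assert_allclose(mr2.points[:, 0], mr.points[:, 0] + 5.0, atol=1e-6)
    np.testing.assert_allclose(mr2.points[:, 1], mr.points[:, 1], atol=1e-6)


def test_mean_route_objective_non_increasing_on_random_population():
    rng = np.random.default_rng(4)
    tracks = []
    for k in range(6):
        lon0 = -100 + rng.normal(0, 1.5)
        wiggle = rng.normal(0, 0.3, 150).cumsum() * 0.05
        lats = np.linspace(58, 22, 150)
        pos = pd.DataFrame({
            "timestamp": pd.date_range("2020-08-01", periods=150, freq="h", tz="UTC"),
            "lon": lon0 + wiggle, "lat": lats, "valid": True})
        tracks.append(InterpolatedTrack(f"b{k}", 2020, "south", pos))
    mr = mean_route(tracks, n=300)
    hist = mr.objective_history
    assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


# ----------------------------------------------------------- band statistics

def test_band_entry_dates_monotone_southward_track():
    # 1 band per day exactly: entry into band [b, b+1) happens at a known time
    n = 30 * 96
    lats = np.linspace(50.0, 20.0, n, endpoint=False)
    pos = pd.DataFrame({
        "timestamp": pd.date_range("2020-08-01", periods=n, freq="15min", tz="UTC"),
        "lon": -100.0, "lat": lats, "valid": True})
    it = InterpolatedTrack("b1", 2020, "south", pos)
    obs = band_entry_dates(it)
    assert set(obs["kind"]) == {"entry_date"}
    start_doy = (pd.Timestamp("2020-08-01", tz="UTC")
                 - pd.Timestamp("2020-01-01", tz="UTC")).days
    row49 = obs[obs["band_low_lat"] == 49]["value"].iloc[0]
    # southward: first position below 50N occurs one step after the start
    assert row49 == pytest.approx(start_doy + 1.0 / 96.0, abs=1e-6)
    row20 = obs[obs["band_low_lat"] == 20]["value"].iloc[0]
    assert row20 == pytest.approx(start_doy + 29.0 + 1.0 / 96.0, abs=0.02)
    # one observation per band crossed (the start point sits on 50.0 exactly)
    assert sorted(obs["band_low_lat"]) == list(range(20, 51))


def test_band_entry_first_entry_wins_on_reentry():
    lats = np.concatenate([np.linspace(45.0, 43.2, 50),
                           np.linspace(43.2, 44.6, 30),   # wanders back north
                           np.linspace(44.6, 40.0, 60)])
    pos = pd.DataFrame({
        "timestamp": pd.date_range("2020-08-01", periods=len(lats), freq="h", tz="UTC"),
        "lon": -100.0, "lat": lats, "valid": True})
    obs = band_entry_dates(InterpolatedTrack("b1", 2020, "south", pos))
    assert (obs["band_low_lat"].value_counts() == 1).all()
    first43 = obs[obs["band_low_lat"] == 43]["value"].iloc[0]
    idx = int(np.argmax(lats < 44.0))
    expected = (pd.Timestamp("2020-08-01", tz="UTC") + pd.Timedelta(hours=idx)
                - pd.Timestamp("2020-01-01", tz="UTC")).total_seconds() / 86400
    assert first43 == pytest.approx(expected, abs=1e-6)


def test_band_entry_track_within_single_band():
    pos = pd.DataFrame({
        "timestamp": pd.date_range("2020-08-01", periods=10, freq="h", tz="UTC"),
        "lon": -100.0, "lat": np.linspace(40.2, 40.8, 10), "valid": True})
    obs = band_entry_dates(InterpolatedTrack("b1", 2020, "south", pos))
    assert len(obs) == 1 and obs["band_low_lat"].iloc[0] == 40


def test_lon_deviation_zero_for_identical_track():
    t = meridian_track(-100.0)
    mr = mean_route([t], n=500)
    dev = band_lon_deviation(t, mr)
    assert np.allclose(dev["value"], 0.0, atol=1e-6)


def test_lon_deviation_one_degree_east_at_45N():
    t_route = meridian_track(-100.0, lat_hi=45.4, lat_lo=44.6)
    mr = mean_route([t_route], n=100)
    t_east = meridian_track(-99.0, lat_hi=45.4, lat_lo=44.6)
    dev = band_lon_deviation(t_east, mr)
    val = dev[dev["band_low_lat"] == 45]["value"].iloc[0]
    assert val == pytest.approx(78.85, abs=1.0)    # geodesic 1° of longitude at 45N
    t_west = meridian_track(-101.0, lat_hi=45.4, lat_lo=44.6)
    dev_w = band_lon_deviation(t_west, mr)
    val_w = dev_w[dev_w["band_low_lat"] == 45]["value"].iloc[0]
    assert val_w == pytest.approx(-val, rel=1e-6)  # mirror image, opposite sign
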