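"""Geographic tracks: Haversine distance, geo buffer model, synthetic tracks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import deploysim as ds
from deploysim.geotrack import EARTH_RADIUS_KM, GeoStationSet, GeoTrack


def reference_haversine(p1, p2):
    """Independent closed-form haversine oracle (explicit formula)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
    h = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _track(lat, lon, animal_id="a"):
    n = len(lat)
    stamps = np.datetime64("2011-01-01") + np.arange(n) * np.timedelta64(1, "h")
    return GeoTrack(animal_id=animal_id, timestamps=stamps, lat=lat, lon=lon)


def test_haversine_known_values():
    assert ds.haversine_km((12.3, -45.6), (12.3, -45.6)) == 0.0
    np.testing.assert_allclose(
        ds.haversine_km((0.0, 0.0), (0.0, 180.0)), np.pi * EARTH_RADIUS_KM, rtol=1e-9
    )
    np.testing.assert_allclose(
        ds.haversine_km((0.0, 0.0), (90.0, 0.0)), np.pi * EARTH_RADIUS_KM / 2, rtol=1e-9
    )
    with pytest.raises(ValueError):
        ds.haversine_km((91.0, 0.0), (0.0, 0.0))
    with pytest.raises(ValueError):
        ds.haversine_km((0.0, 181.0), (0.0, 0.0))


@given(
    lat1=st.floats(-90, 90), lon1=st.floats(-180, 180),
    lat2=st.floats(-90, 90), lon2=st.floats(-180, 180),
    lat3=st.floats(-90, 90), lon3=st.floats(-180, 180),
)
def test_haversine_metric_properties_vs_oracle(lat1, lon1, lat2, lon2, lat3, lon3):
    p1, p2, p3 = (lat1, lon1), (lat2, lon2), (lat3, lon3)
    d12 = ds.haversine_km(p1, p2)
    assert d12 >= 0.0
    np.testing.assert_allclose(d12, ds.haversine_km(p2, p1), atol=1e-9)
    np.testing.assert_allclose(d12, reference_haversine(p1, p2), atol=1e-6)
    assert d12 <= ds.haversine_km(p1, p3) + ds.haversine_km(p3, p2) + 1e-6


def test_run_geo_trivial_cases():
    track = _track([0.0, 0.01, 0.02], [0.0, 0.0, 0.0])
    near = GeoStationSet(lat=[0.01], lon=[0.0], radius_km=500.0)
    res = ds.run_geo([track], near)
    assert res.T_mean == 1.0
    far = GeoStationSet(lat=[45.0], lon=[90.0], radius_km=10.0)
    res = ds.run_geo([track], far)
    assert res.T_mean == 0.0
    assert res.stored[0] == 3
    np.testing.assert_array_equal(res.generated, res.transmitted + res.stored)


def test_run_geo_buffer_trace_k_then_flush():
    # 4 fixes far from the station, then one inside: single event of size 5
    lat = [10.0, 10.0, 10.0, 10.0, 0.0]
    lon = [100.0, 100.0, 100.0, 100.0, 0.0]
    station = GeoStationSet(lat=[0.0], lon=[0.0], radius_km=50.0)
    res = ds.run_geo([_track(lat, lon)], station)
    np.testing.assert_array_equal(res.log.event_times[0], [5])
    np.testing.assert_array_equal(res.log.event_sizes[0], [5])
    assert res.T_mean == 1.0


def test_run_geo_range_test_is_strict():
    # fix exactly at radius distance does NOT flush (strict < for geo tracks)
    d = ds.haversine_km((0.0, 0.0), (0.0, 1.0))
    track = _track([0.0], [1.0])
    at_radius = GeoStationSet(lat=[0.0], lon=[0.0], radius_km=d)
    assert ds.run_geo([track], at_radius).T_mean == 0.0
    inside = GeoStationSet(lat=[0.0], lon=[0.0], radius_km=d + 1e-6)
    assert ds.run_geo([track], inside).T_mean == 1.0


def test_place_geo_random_contract(strong_tracks):
    st10 = ds.place_geo_random(strong_tracks, 10, 50.0, rng_seed=1)
    assert len(st10) == 10
    lats = np.concatenate([t.lat for t in strong_tracks])
    lons = np.concatenate([t.lon for t in strong_tracks])
    assert st10.lat.min() >= lats.min() and st10.lat.max() <= lats.max()
    assert st10.lon.min() >= lons.min() and st10.lon.max() <= lons.max()
    assert len(ds.place_geo_random(strong_tracks, 0, 50.0, rng_seed=1)) == 0
    again = ds.place_geo_random(strong_tracks, 10, 50.0, rng_seed=1)
    np.testing.assert_array_equal(st10.lat, again.lat)
    single = _track([1.0], [2.0])
    with pytest.raises(ValueError):
        ds.place_geo_random([single], 3, 50.0, rng_seed=1)


def test_place_geo_at_homes_uses_first_fixes(strong_tracks):
    n = len(strong_tracks)
    sts = ds.place_geo_at_homes(strong_tracks, n, 50.0, rng_seed=2)
    first = {(t.lat[0], t.lon[0]) for t in strong_tracks}
    got = set(zip(sts.lat, sts.lon))
    assert got == first
    one = ds.place_geo_at_homes(strong_tracks, 1, 50.0, rng_seed=3)
    assert (one.lat[0], one.lon[0]) in first


def test_synthetic_tracks_reproducible_and_regime_extents():
    cfg = ds.synth_config("strong", n_animals=5, n_steps=200, seed=9)
    t1 = ds.generate_synthetic_geotracks(cfg)
    t2 = ds.generate_synthetic_geotracks(cfg)
    for a, b in zip(t1, t2):
        np.testing.assert_array_equal(a.lat, b.lat)
        np.testing.assert_array_equal(a.lon, b.lon)

    # weak-attraction animals travel much farther from their homes
    weak = ds.generate_synthetic_geotracks(
        ds.synth_config("weak", n_animals=5, n_steps=200, seed=9)
    )
    def max_range_km(tracks):
        return max(
            max(ds.haversine_km((t.lat[0], t.lon[0]), (la, lo))
                for la, lo in zip(t.lat, t.lon))
            for t in tracks
        )
    assert max_range_km(weak) > 3 * max_range_km(t1)


def test_synthetic_full_attraction_circles_through_tangent_plane():
    cfg = ds.GeoSynthConfig(
        a=1.0, home_lat=-40.0, home_lon=100.0, step_km=5.0,
        n_steps=50, n_animals=3, seed=4, home_spread_km=0.0,
    )
    tracks = ds.generate_synthetic_geotracks(cfg)
    for tr in tracks:
        home = (tr.lat[0], tr.lon[0])
        d = np.array([ds.haversine_km(home, (la, lo)) for la, lo in zip(tr.lat[1:], tr.lon[1:])])
        np.testing.assert_allclose(d, 5.0, rtol=5e-3)


def test_synth_config_validation():
    with pytest.raises(ValueError):
        ds.synth_config("martian")
    with pytest.raises(ValueError):
        ds.GeoSynthConfig(a=0.5, home_lat=89.5, home_lon=0.0, step_km=5.0,
                          n_steps=10, n_animals=1, seed=0)


def test_transfer_vs_area_geo_area_axis_and_fit(weak_tracks):
    sweep, fit = ds.transfer_vs_area_geo(
        weak_tracks, [0, 2, 5, 10, 20], radius_km=50.0, n_realizations=4, seed=5
    )
    row10 = sweep.table[sweep.table["n_stations"] == 10].iloc[0]
    np.testing.assert_allclose(row10["covered_area"], 78539.8, atol=0.05)
    zero = sweep.table[sweep.table["n_stations"] == 0].iloc[0]
    assert zero["T_mean"] == 0.0
    assert fit.params["d"] > 0


def test_weak_attraction_tracks_have_larger_growth_rate(weak_tracks, strong_tracks):
    """Per km^2 of deployed reception area, wide-ranging (weak-attraction)
    animals yield a faster-growing transfer curve than coastal
    (strong-attraction) ones at equal station counts and radius."""
    counts = [0, 1, 2, 4, 8, 16]
    _, fit_weak = ds.transfer_vs_area_geo(weak_tracks, counts, 30.0, 4, seed=6)
    _, fit_strong = ds.transfer_vs_area_geo(strong_tracks, counts, 30.0, 4, seed=6)
    assert fit_weak.params["d"] > fit_strong.params["d"]


def test_tracks_csv_roundtrip(tmp_path, strong_tracks):
    path = tmp_path / "tracks.csv"
    ds.write_tracks_csv(path, strong_tracks)
    back = ds.read_tracks_csv(path)
    assert len(back) == len(strong_tracks)
    by_id = {t.animal_id: t for t in back}
    for tr in strong_tracks:
        got = by_id[tr.animal_id]
        np.testing.assert_allclose(got.lat, tr.lat, atol=1e-9)
        np.testing.assert_allclose(got.lon, tr.lon, atol=1e-9)
        np.testing.assert_array_equal(got.timestamps, tr.timestamps)


def test_geotrack_validation():
    with pytest.raises(ValueError):
        _track([0.0, 95.0], [0.0, 0.0])
    stamps = np.array(["2011-01-02", "2011-01-01"], dtype="datetime64[s]")
    with pytest.raises(ValueError):
        GeoTrack(animal_id="b", timestamps=stamps, lat=[0, 0], lon=[0, 0])
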