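"""Country/coastline validation against closed-form and brute-force oracles."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon, box

from occurclean.datamodel import OccurrenceRecord, TaxonName
from occurclean.geovalidate import (
    EARTH_RADIUS_KM,
    Classification,
    CountryPolygonSet,
    density_grid,
    haversine_km,
    nearest_border_distance_km,
    validate_coastline,
    validate_country,
    validate_records,
)

KM_PER_DEG = 2 * math.pi * EARTH_RADIUS_KM / 360  # ~111.1949 at the equator


def _rec(rid, lat, lon, country):
    return OccurrenceRecord(rid, taxon=TaxonName(genus="G"), latitude=lat, longitude=lon, country_code=country)


# --- classification --------------------------------------------------------


def test_point_inside_documented_country_is_match_keep(two_countries):
    res = validate_country(_rec("r", 0.0, 11.0, "XAA"), two_countries)
    assert res.classification is Classification.Match
    assert res.keep and res.distance_km is None


def test_point_across_adjacent_border_within_tolerance_is_neighbour_keep(two_countries):
    # 3 km east of the XAA/XAB border at lon=12, documented XAA
    lon = 12.0 + 3.0 / KM_PER_DEG
    res = validate_country(_rec("r", 0.0, lon, "XAA"), two_countries)
    assert res.classification is Classification.Neighbour
    assert res.distance_km == pytest.approx(3.0, rel=0.01)
    assert res.keep


def test_point_across_adjacent_border_beyond_tolerance_is_discarded(two_countries):
    lon = 12.0 + 7.0 / KM_PER_DEG
    res = validate_country(_rec("r", 0.0, lon, "XAA"), two_countries)
    assert res.classification is Classification.Neighbour
    assert res.distance_km == pytest.approx(7.0, rel=0.01)
    assert not res.keep


def test_point_in_non_adjacent_country_is_error_discard(three_countries):
    res = validate_country(_rec("r", 0.0, 17.0, "XAA"), three_countries)
    assert res.classification is Classification.Error
    assert not res.keep


def test_offshore_point_near_coast_kept_far_discarded(two_countries):
    near = validate_coastline(_rec("r", 0.0, 10.0 - 2.0 / KM_PER_DEG, "XAA"), two_countries)
    far = validate_coastline(_rec("r", 0.0, 10.0 - 40.0 / KM_PER_DEG, "XAA"), two_countries)
    assert near.classification is Classification.Sea and near.keep
    assert near.distance_km == pytest.approx(2.0, rel=0.01)
    assert far.classification is Classification.Sea and not far.keep


def test_offshore_point_without_documented_country_is_discarded(two_countries):
    res = validate_coastline(_rec("r", 0.0, 9.9, None), two_countries)
    assert not res.keep


def test_point_exactly_on_border_counts_as_match(two_countries):
    res = validate_country(_rec("r", 0.0, 12.0, "XAA"), two_countries)
    assert res.classification is Classification.Match and res.keep


def test_distance_exactly_at_tolerance_is_kept(two_countries):
    res = validate_country(_rec("r", 0.0, 12.0 + 3.0 / KM_PER_DEG, "XAA"), two_countries, tolerance_km=3.0)
    assert res.distance_km == pytest.approx(3.0, rel=0.01)
    assert res.keep


def test_missing_coordinates_and_missing_country(two_countries):
    no_coord = validate_country(_rec("r", None, None, "XAA"), two_countries)
    assert no_coord.classification is Classification.NoCoordinates and not no_coord.keep
    no_country = validate_country(_rec("r", 0.0, 11.0, None), two_countries)
    assert no_country.classification is Classification.NoCountry and no_country.keep


def test_country_check_dispatches_ocean_points_to_sea(two_countries):
    res = validate_country(_rec("r", 0.0, 9.99, "XAA"), two_countries)
    assert res.classification is Classification.Sea


# --- distance function ------------------------------------------------------


def test_point_on_polygon_vertex_has_zero_distance(two_countries):
    assert nearest_border_distance_km((1.0, 10.0), two_countries.polygons["XAA"]) == pytest.approx(0.0, abs=1e-6)


def test_meridian_border_closed_form_distance():
    # 1 degree due east of a meridian segment at the equator
    boundary = CountryPolygonSet({"XAA": box(10, -1, 12, 1)})
    d = nearest_border_distance_km((0.0, 13.0), boundary.polygons["XAA"])
    assert d == pytest.approx(KM_PER_DEG, rel=1e-3)  # ~111.19 km


def test_distance_matches_brute_force_vertex_sweep():
    """Independent oracle: sample the boundary at 0.0001 deg and sweep in pure python."""
    poly = Polygon([(10, -1), (12, -1), (12.7, 0.3), (11, 1.2), (10, -1)])
    rng = random.Random(7)
    coords = list(poly.exterior.coords)
    for _ in range(5):
        lat, lon = rng.uniform(-2, 2), rng.uniform(9, 14)
        best = math.inf
        for (x1, y1), (x2, y2) in zip(coords, coords[1:]):
            seg_len = math.hypot(x2 - x1, y2 - y1)
            n = max(2, int(seg_len / 0.0001))
            for t in np.linspace(0.0, 1.0, n):
                best = min(best, haversine_km(lat, lon, y1 + t * (y2 - y1), x1 + t * (x2 - x1)))
        got = nearest_border_distance_km((lat, lon), poly)
        assert got == pytest.approx(best, rel=1e-3)


def test_empty_boundary_is_hard_error():
    with pytest.raises(ValueError):
        nearest_border_distance_km((0.0, 0.0), np.empty((0, 2)))


@given(
    lat=st.floats(-60, 60),
    lon=st.floats(-170, 170),
    shift=st.floats(-5, 5),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_haversine_invariant_under_longitude_shift_and_symmetric(lat, lon, shift):
    d1 = haversine_km(lat, lon, lat + 1.0, lon + 1.0)
    d2 = haversine_km(lat, lon + shift, lat + 1.0, lon + 1.0 + shift)
    assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-9)
    assert haversine_km(lat, lon, lat + 1.0, lon + 1.0) == pytest.approx(
        haversine_km(lat + 1.0, lon + 1.0, lat, lon), rel=1e-12
    )


# --- point-in-polygon oracle -----------------------------------------------


def _ray_cast(poly_coords, x, y):
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xin:
                inside = not inside
    return inside


def test_point_in_polygon_agrees_with_ray_casting_oracle():
    rng = random.Random(3)
    for trial in range(10):
        pts = [(rng.uniform(0, 4), rng.uniform(0, 4)) for _ in range(5)]
        hull = Polygon(pts).convex_hull
        if hull.geom_type != "Polygon":
            continue
        coords = list(hull.exterior.coords)[:-1]
        for _ in range(50):
            x, y = rng.uniform(-1, 5), rng.uniform(-1, 5)
            if hull.boundary.distance(Point(x, y)) < 1e-9:
                continue  # oracle is ill-defined exactly on the edge
            assert hull.contains(Point(x, y)) == _ray_cast(coords, x, y)


# --- invariants -------------------------------------------------------------


def test_every_record_classified_once_and_verdicts_partition(small_fixture):
    results = validate_records(small_fixture.records, small_fixture.polygons)
    assert set(results) == {r.record_id for r in small_fixture.records}
    kept = {rid for rid, r in results.items() if r.keep}
    discarded = {rid for rid, r in results.items() if not r.keep}
    assert kept | discarded == set(results) and not kept & discarded


def test_shrinking_tolerance_never_converts_discard_to_keep(small_fixture):
    wide = validate_records(small_fixture.records, small_fixture.polygons, tolerance_km=5.0)
    narrow = validate_records(small_fixture.records, small_fixture.polygons, tolerance_km=1.0)
    for rid in wide:
        if not wide[rid].keep:
            assert not narrow[rid].keep


# --- density grid -----------------------------------------------------------


def test_density_grid_single_cell():
    recs = [_rec(f"r{i}", 0.5, 10.5, "XAA") for i in range(10)]
    grid = density_grid(recs, cell_degrees=2.0)
    assert len(grid) == 1 and grid["count"].iloc[0] == 10
    assert grid["lon_min"].iloc[0] == 10.0 and grid["lat_min"].iloc[0] == 0.0


def test_density_grid_edge_record_assigned_half_open():
    grid = density_grid([_rec("r", 2.0, 12.0, "XAA")], cell_degrees=2.0)
    assert (grid["lon_min"].iloc[0], grid["lat_min"].iloc[0]) == (12.0, 2.0)


def test_density_grid_conserves_total_count():
    rng = random.Random(1)
    recs = [
        _rec(f"r{i}", rng.uniform(-30, 30), rng.uniform(-20, 50), "XAA") for i in range(1000)
    ]
    grid = density_grid(recs, cell_degrees=2.0)
    assert grid["count"].sum() == 1000


def test_density_grid_rejects_nonpositive_cell():
    with pytest.raises(ValueError):
        density_grid([], cell_degrees=0)
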