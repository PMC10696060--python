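"""Beam geometry and the clutter-mitigation chain."""
import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopover_radar.config import StationSpec
from stopover_radar.grids import Grid
from stopover_radar.scans import (
    FLAG_PRECIP,
    FLAG_VALID,
    PolarGeometry,
    PolarMask,
    apply_mask,
    apply_precipitation_mask,
    beam_height,
    dbz_to_linear,
    exclusion_mask,
    pod_clutter_mask,
    select_clear_scans,
    topographic_clutter_mask,
)

from conftest import make_scan

TOY_GEO = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=1.0, max_range_km=2.0)


def test_beam_height_at_zero_range_is_antenna_height():
    assert beam_height(0.0, 0.5, 30.0) == pytest.approx(30.0)
    assert beam_height(0.0, 4.5, 30.0) == pytest.approx(30.0)


def test_beam_height_standard_refraction_closed_form():
    # independent evaluation of the 4/3-earth formula
    r, theta, rp = 80.0, np.deg2rad(0.5), 4.0 / 3.0 * 6371.0
    expected = (np.sqrt(r**2 + rp**2 + 2 * r * rp * np.sin(theta)) - rp) * 1000.0
    assert beam_height(80.0, 0.5, 0.0) == pytest.approx(expected)
    assert expected == pytest.approx(1075.0, abs=2.0)


def test_beam_height_monotone_in_range_and_elevation():
    r = np.linspace(0.5, 150, 200)
    h1 = beam_height(r, 0.5, 0.0)
    h2 = beam_height(r, 1.5, 0.0)
    assert np.all(np.diff(h1) > 0)
    assert np.all(h2 > h1)


def test_beam_height_negative_range_errors():
    with pytest.raises(ValueError):
        beam_height(-1.0, 0.5)


# ---------------------------------------------------------------------------
# topographic mask
# ---------------------------------------------------------------------------


def _flat_world(elev_value=0.0, size=320):
    grid = Grid(nx=size, ny=size)
    elev = np.full(grid.shape, elev_value)
    station = StationSpec("T01", size / 2.0, size / 2.0)
    return grid, elev, station


def test_topographic_mask_empty_over_flat_terrain():
    grid, elev, station = _flat_world(0.0)
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=100.0)
    mask = topographic_clutter_mask(station, elev, grid, geo)
    assert not mask.cells.any()


def test_topographic_mask_wall_blocks_low_beam_until_it_climbs():
    grid, elev, station = _flat_world(0.0)
    # a 2000-m wall at ~20 km due east
    iy, ix = grid.pixel_index(station.x_km + 20.0, station.y_km)
    elev[iy - 3 : iy + 4, ix - 1 : ix + 2] = 2000.0
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=150.0)
    mask = topographic_clutter_mask(station, elev, grid, geo)
    low = mask.layer(0.5)
    east = int(90.0 / geo.azimuth_step_deg)  # azimuth 90 deg = east
    r = geo.gate_centers_km()
    lower_edge = (
        beam_height(r, 0.5, station.antenna_height_m)
        - r * 1000.0 * np.deg2rad(1.0) / 2.0
    )
    flagged = low[east]
    assert flagged.any()
    r_wall = r[flagged].min()
    assert 18.5 <= r_wall <= 21.5
    # every gate beyond the wall is flagged exactly while the lower beam edge
    # sits at or below 2000 m (inverting the beam-height relation), and gates
    # before the wall stay clear
    np.testing.assert_array_equal(flagged, (r >= r_wall) & (lower_edge <= 2000.0))
    assert not flagged[r < r_wall].any()
    # on a steeper sweep the lower edge clears 2000 m within range, and gates
    # beyond that point unflag again (no permanent occlusion)
    high = mask.layer(4.5)[east]
    lower_edge_45 = (
        beam_height(r, 4.5, station.antenna_height_m)
        - r * 1000.0 * np.deg2rad(1.0) / 2.0
    )
    np.testing.assert_array_equal(high, (r >= r_wall) & (lower_edge_45 <= 2000.0))
    assert high.any() and not high[-1]


def test_topographic_mask_is_static_and_idempotent():
    grid, elev, station = _flat_world(0.0)
    elev[100, 200] = 1500.0
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=100.0)
    mask = topographic_clutter_mask(station, elev, grid, geo)
    rng = np.random.default_rng(0)
    scan = make_scan({0.5: rng.normal(10, 3, (geo.n_az, geo.n_gates))}, geo)
    apply_mask(scan, mask)
    once = scan.sweeps[0].dbz.copy()
    apply_mask(scan, mask)
    np.testing.assert_array_equal(scan.sweeps[0].dbz, once)


def test_topographic_mask_station_outside_raster_errors():
    grid, elev, _ = _flat_world()
    with pytest.raises(ValueError):
        topographic_clutter_mask(StationSpec("X", -5.0, 10.0), elev, grid, TOY_GEO)


# ---------------------------------------------------------------------------
# clear-scan selection
# ---------------------------------------------------------------------------


def _winter_scan(dbz_value, ts, geo=None):
    geo = geo or PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=5.0)
    return make_scan(
        {0.5: np.full((geo.n_az, geo.n_gates), float(dbz_value))}, geo, timestamp=ts
    )


def test_select_clear_scans_tie_break_and_count():
    t0 = dt.datetime(2020, 1, 2)
    scans = [_winter_scan(0.0, t0 + dt.timedelta(minutes=i)) for i in range(40)]
    out = select_clear_scans(scans, n_pool=40, n_select=30)
    assert len(out) == 30  # the 30 lowest-reflectivity scans are kept
    assert [s.timestamp for s in out] == [s.timestamp for s in scans[:30]]


def test_select_clear_scans_matches_bruteforce_ranking():
    rng = np.random.default_rng(8)
    t0 = dt.datetime(2020, 1, 2)
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=3.0)
    scans = []
    for i in range(12):
        scans.append(
            make_scan(
                {0.5: rng.normal(5, 10, (geo.n_az, geo.n_gates))},
                geo,
                timestamp=t0 + dt.timedelta(minutes=i),
            )
        )
    out = select_clear_scans(scans, n_pool=12, n_select=4, clip_dbz=35.0)
    totals = [
        float(dbz_to_linear(np.minimum(s.sweeps[0].dbz, 35.0)).sum()) for s in scans
    ]
    expected = [scans[i].timestamp for i in np.argsort(totals)[:4]]
    assert [s.timestamp for s in out] == expected


def test_select_clear_scans_clipping_caps_strong_echoes():
    t0 = dt.datetime(2020, 1, 2)
    hot = _winter_scan(60.0, t0)  # clipped to 35 dBZ before totalling
    warm = _winter_scan(35.0, t0 + dt.timedelta(minutes=1))
    cool = _winter_scan(0.0, t0 + dt.timedelta(minutes=2))
    out = select_clear_scans([hot, warm, cool], n_pool=3, n_select=2)
    # hot and warm tie after clipping; the earlier (hot) wins the tie
    assert [s.timestamp for s in out] == [cool.timestamp, hot.timestamp]


def test_select_clear_scans_requires_enough_scans():
    with pytest.raises(ValueError):
        select_clear_scans([_winter_scan(0, dt.datetime(2020, 1, 2))], n_select=30)


# ---------------------------------------------------------------------------
# POD clutter mask
# ---------------------------------------------------------------------------


def _pod_scans(hit_fraction_by_cell, n_scans, year, geo):
    """Scans whose cell (0, g) exceeds 10 dBZ in a given fraction of scans."""
    scans = []
    for i in range(n_scans):
        dbz = np.full((geo.n_az, geo.n_gates), -5.0)
        for (az, g), frac in hit_fraction_by_cell.items():
            if i < round(frac * n_scans):
                dbz[az, g] = 25.0
        scans.append(
            make_scan({0.5: dbz}, geo, timestamp=dt.datetime(year, 1, 2, 0, i))
        )
    return scans


def test_pod_threshold_inclusive_two_year_rule():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=1.0, max_range_km=2.0)
    # POD exactly 0.20 (6 of 30) in both years -> clutter
    by_year = {
        y: _pod_scans({(0, 1): 0.2}, 30, y, geo) for y in (2019, 2020)
    }
    mask = pod_clutter_mask(by_year)
    assert mask.layer(0.5)[0, 1]
    # always below 10 dBZ -> never clutter
    assert not mask.layer(0.5)[1:].any()


def test_pod_single_year_exceedance_is_not_clutter():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=1.0, max_range_km=2.0)
    by_year = {
        2019: _pod_scans({(3, 0): 1.0}, 30, 2019, geo),
        2020: _pod_scans({}, 30, 2020, geo),
    }
    mask = pod_clutter_mask(by_year)
    assert not mask.layer(0.5).any()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n_years=st.integers(1, 3),
    n_scans=st.integers(1, 8),
)
def test_pod_mask_matches_exhaustive_counting(seed, n_years, n_scans):
    """Oracle: exhaustive per-cell exceedance counting on random scan sets."""
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=1.0, max_range_km=1.0)
    rng = np.random.default_rng(seed)
    by_year = {}
    dbz_by_year = {}
    for y in range(2018, 2018 + n_years):
        arrs = [rng.uniform(-10, 30, (geo.n_az, geo.n_gates)) for _ in range(n_scans)]
        dbz_by_year[y] = arrs
        by_year[y] = [
            make_scan({0.5: a}, geo, timestamp=dt.datetime(y, 1, 2, 0, i))
            for i, a in enumerate(arrs)
        ]
    mask = pod_clutter_mask(by_year, pod_dbz=10.0, pod_frac=0.20, min_years=2)
    expected = np.zeros((geo.n_az, geo.n_gates), dtype=int)
    for y, arrs in dbz_by_year.items():
        pod = np.mean([a > 10.0 for a in arrs], axis=0)
        expected += pod >= 0.20
    np.testing.assert_array_equal(mask.layer(0.5), expected >= 2)


# ---------------------------------------------------------------------------
# precipitation masking
# ---------------------------------------------------------------------------


def _bird_scan(geo, value=10.0):
    return make_scan({0.5: np.full((geo.n_az, geo.n_gates), value)}, geo)


def test_empty_precip_mask_is_a_noop():
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=90.0)
    scan = _bird_scan(geo)
    before = scan.sweeps[0].dbz.copy()
    mask = PolarMask("T01", geo, np.zeros((geo.n_az, geo.n_gates), dtype=bool))
    _, rejected = apply_precipitation_mask(scan, mask)
    assert not rejected
    np.testing.assert_array_equal(scan.sweeps[0].dbz, before)


def test_precip_dilation_is_ground_distance():
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=90.0)
    scan = _bird_scan(geo)
    cells = np.zeros((geo.n_az, geo.n_gates), dtype=bool)
    az0, g0 = 90, 79  # one voxel at 39.75 km due east
    cells[az0, g0] = True
    mask = PolarMask("T01", geo, cells)
    _, rejected = apply_precipitation_mask(scan, mask, dilate_km=5.0)
    assert not rejected
    dx, dy = geo.ground_offsets_km()
    dist = np.hypot(dx - dx[az0, g0], dy - dy[az0, g0])
    flagged = scan.sweeps[0].flags == FLAG_PRECIP
    np.testing.assert_array_equal(flagged, dist <= 5.0)
    assert flagged.sum() > 1  # the buffer reaches neighbouring azimuths


def test_precip_rejection_is_strictly_greater_than_30pct():
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=90.0)
    r = geo.gate_centers_km()
    annulus_gates = np.nonzero((r >= 7.5) & (r < 80.0))[0]
    n_annulus = geo.n_az * len(annulus_gates)

    def run(frac):
        scan = _bird_scan(geo)
        cells = np.zeros((geo.n_az, geo.n_gates), dtype=bool)
        k = int(round(frac * n_annulus))
        az, g = np.unravel_index(np.arange(k), (geo.n_az, len(annulus_gates)))
        cells[az, annulus_gates[g]] = True
        mask = PolarMask("T01", geo, cells)
        # zero dilation isolates the threshold rule
        return apply_precipitation_mask(scan, mask, dilate_km=0.0)[1]

    assert run(0.31) is True
    assert run(0.30) is False


def test_precip_geometry_mismatch_errors():
    scan = _bird_scan(TOY_GEO)
    other = PolarGeometry(gate_depth_m=250, azimuth_step_deg=0.5, max_range_km=2.0)
    mask = PolarMask("T01", other, np.zeros((other.n_az, other.n_gates), dtype=bool))
    with pytest.raises(ValueError):
        apply_precipitation_mask(scan, mask)


def test_exclusion_buffer_masks_a_disc_in_domain_coordinates():
    geo = PolarGeometry(gate_depth_m=500, azimuth_step_deg=1.0, max_range_km=50.0)
    station = StationSpec("T01", 100.0, 100.0)
    mask = exclusion_mask(station, geo, ((120.0, 100.0, 3.0),))
    dx, dy = geo.ground_offsets_km()
    expected = np.hypot(dx - 20.0, dy - 0.0) <= 3.0
    np.testing.assert_array_equal(mask.cells, expected)
    assert mask.cells.any()
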