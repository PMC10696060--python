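"""Night curves, exodus GAM, VPR estimation, range correction, mosaicking."""
import datetime as dt

import numpy as np
import pytest

from stopover_radar.config import StationSpec
from stopover_radar.grids import Grid
from stopover_radar.measurement import (
    VPR,
    NightCurve,
    StopoverRaster,
    estimate_vpr,
    fit_exodus_time,
    median_reflectivity_series,
    mosaic_stations,
    range_correct,
    seasonal_station_raster,
    select_night_scan,
)
from stopover_radar.scans import PolarGeometry, beam_height, beam_sd_m, dbz_to_linear

from conftest import make_scan


# ---------------------------------------------------------------------------
# median reflectivity
# ---------------------------------------------------------------------------


def _series_geo():
    return PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=4.5)


def test_median_series_constant_scan():
    geo = _series_geo()
    scans = [
        make_scan(
            {0.5: np.full((geo.n_az, geo.n_gates), 10.0)},
            geo,
            timestamp=dt.datetime(2020, 5, 1, 19, 0) + dt.timedelta(minutes=10 * i),
            minutes_after_sunset=10.0 * i,
        )
        for i in range(3)
    ]
    curve = median_reflectivity_series(scans)
    np.testing.assert_allclose(curve.median_eta, dbz_to_linear(10.0))
    np.testing.assert_allclose(curve.minutes, [0.0, 10.0, 20.0])


def test_median_series_half_zero_half_2c():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=45.0, max_range_km=4.5)
    dbz = np.empty((geo.n_az, geo.n_gates))  # 72 voxels: an even split
    c = 50.0  # linear units
    flat = dbz.reshape(-1)
    half = flat.size // 2
    flat[:half] = 10.0 * np.log10(2 * c)
    flat[half:] = -50.0  # effectively zero linear reflectivity
    scan = make_scan({0.5: dbz}, geo, minutes_after_sunset=0.0)
    curve = median_reflectivity_series([scan])
    assert curve.median_eta[0] == pytest.approx(c, rel=1e-4)


def test_median_series_matches_hand_sorted_toy():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=0.5)
    rng = np.random.default_rng(4)
    dbz = rng.uniform(-5, 30, (geo.n_az, geo.n_gates))  # 9 voxels
    scan = make_scan({0.5: dbz}, geo, minutes_after_sunset=0.0)
    curve = median_reflectivity_series([scan])
    assert curve.median_eta[0] == pytest.approx(sorted(dbz_to_linear(dbz).ravel())[4])


# ---------------------------------------------------------------------------
# exodus time
# ---------------------------------------------------------------------------


def _logistic_curves(midpoint, n_nights=5, offsets=None, scale=10.0):
    minutes = np.arange(0.0, 151.0, 10.0)
    curves = []
    for i in range(n_nights):
        c = offsets[i] if offsets else 0.0
        eta = 100.0 / (1.0 + np.exp(-(minutes - midpoint) / scale)) + c
        curves.append(
            NightCurve("T01", dt.date(2020, 5, 1 + i), minutes, eta)
        )
    return curves


def test_exodus_recovers_logistic_midpoint():
    t = fit_exodus_time(_logistic_curves(45.0))
    assert abs(t - 45.0) <= 5.0


def test_exodus_linear_ramp_ties_to_earliest():
    minutes = np.arange(0.0, 151.0, 10.0)
    curves = [
        NightCurve("T01", dt.date(2020, 5, 1 + i), minutes, 2.0 * minutes + 5.0)
        for i in range(4)
    ]
    assert fit_exodus_time(curves) == 0.0


def test_exodus_date_offsets_absorbed():
    base = fit_exodus_time(_logistic_curves(60.0))
    shifted = fit_exodus_time(_logistic_curves(60.0, offsets=[0, 40, -30, 15, 5]))
    assert abs(base - shifted) <= 2.0


def test_exodus_constant_series_errors():
    minutes = np.arange(0.0, 151.0, 10.0)
    curves = [
        NightCurve("T01", dt.date(2020, 5, 1 + i), minutes, np.full_like(minutes, 7.0))
        for i in range(4)
    ]
    with pytest.raises(ValueError, match="no exodus signal"):
        fit_exodus_time(curves)


def test_exodus_needs_three_nights():
    with pytest.raises(ValueError):
        fit_exodus_time(_logistic_curves(45.0, n_nights=2))


def test_select_night_scan_nearest_with_tie_to_earlier():
    geo = _series_geo()
    scans = [
        make_scan(
            {0.5: np.zeros((geo.n_az, geo.n_gates))}, geo,
            timestamp=dt.datetime(2020, 5, 1, 19) + dt.timedelta(minutes=m),
            minutes_after_sunset=float(m),
        )
        for m in (30, 40, 50)
    ]
    assert select_night_scan(scans, [False] * 3, 45.0).minutes_after_sunset == 40.0
    # exact tie (30 and 50 both 10 min from exodus) breaks to the earlier scan
    assert select_night_scan(scans, [False, True, False], 40.0).minutes_after_sunset == 30.0
    assert select_night_scan(scans, [True] * 3, 45.0) is None


# ---------------------------------------------------------------------------
# VPR
# ---------------------------------------------------------------------------


def test_vpr_needs_two_sweeps():
    geo = _series_geo()
    scan = make_scan({0.5: np.zeros((geo.n_az, geo.n_gates))}, geo)
    with pytest.raises(ValueError):
        estimate_vpr(scan)


def test_vpr_empty_pool_errors():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=2.0)
    scan = make_scan(
        {0.5: np.zeros((geo.n_az, geo.n_gates)), 1.5: np.zeros((geo.n_az, geo.n_gates))},
        geo,
    )  # no gates beyond 5 km
    with pytest.raises(ValueError):
        estimate_vpr(scan)


def test_vpr_bins_by_beam_center_height():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=36.0)
    r = geo.gate_centers_km()
    vals = {}
    for el in (0.5, 2.5):
        h = beam_height(r, el, 30.0)
        dbz = np.tile(10.0 * np.log10(1.0 + h), (geo.n_az, 1))  # eta = 1 + height
        vals[el] = dbz
    scan = make_scan(vals, geo)
    vpr = estimate_vpr(scan, antenna_height_m=30.0)
    # eta in each populated bin should average to ~1 + bin center height
    # (the lowest bins sample beam heights unevenly and are excluded)
    populated = (vpr.density > 0) & (vpr.altitude_mid_m >= 200.0)
    assert populated.sum() >= 8
    mids = vpr.altitude_mid_m[populated]
    np.testing.assert_allclose(vpr.density[populated], 1.0 + mids, rtol=0.12)


# ---------------------------------------------------------------------------
# range correction
# ---------------------------------------------------------------------------


def _delta_vpr(bin_idx, n_bins=20):
    density = np.zeros(n_bins)
    density[bin_idx] = 5.0
    return VPR(altitude_mid_m=(np.arange(n_bins) + 0.5) * 100.0, density=density)


def _grid_and_station():
    grid = Grid(nx=200, ny=200)
    return grid, StationSpec("T01", 100.0, 100.0)


def test_range_correct_factor_is_inverse_gaussian_overlap():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=60.0)
    grid, station = _grid_and_station()
    dbz = np.full((geo.n_az, geo.n_gates), 20.0)
    scan = make_scan({0.5: dbz}, geo, minutes_after_sunset=45.0)
    vpr = _delta_vpr(4)  # all mass at 450 m
    out = range_correct(scan, vpr, station, grid, "spring", 2019)
    r = geo.gate_centers_km()
    hc = beam_height(r, 0.5, station.antenna_height_m)
    w = np.exp(-((450.0 - hc) ** 2) / (2.0 * beam_sd_m(r) ** 2))
    # pick a mid-range gate: corrected = measured / w * bin depth
    g = np.argmin(np.abs(r - 38.4))  # beam center ~450 m here, w ~ 1
    assert w[g] > 0.999
    dx, dy = geo.ground_offsets_km()
    iy, ix = grid.pixel_index(station.x_km + dx[0, g], station.y_km + dy[0, g])
    expected = dbz_to_linear(20.0) / w[g] * 0.1
    assert out.values[iy, ix] == pytest.approx(expected, rel=1e-3)


def test_range_correct_factor_two_when_half_mass_visible():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=60.0)
    grid, station = _grid_and_station()
    dbz = np.full((geo.n_az, geo.n_gates), 20.0)
    scan = make_scan({0.5: dbz}, geo, minutes_after_sunset=45.0)
    # half the mass at the beam center near 38.4 km, half far above the beam
    density = np.zeros(20)
    density[4] = 1.0
    density[19] = 1.0
    vpr = VPR(altitude_mid_m=(np.arange(20) + 0.5) * 100.0, density=density)
    out = range_correct(scan, vpr, station, grid, "spring", 2019)
    r = geo.gate_centers_km()
    g = np.argmin(np.abs(r - 38.4))
    dx, dy = geo.ground_offsets_km()
    iy, ix = grid.pixel_index(station.x_km + dx[0, g], station.y_km + dy[0, g])
    expected = dbz_to_linear(20.0) * 2.0 * 0.1  # factor 2
    assert out.values[iy, ix] == pytest.approx(expected, rel=2e-2)


def test_range_correct_caps_factor_and_range():
    geo = PolarGeometry(gate_depth_m=500.0, azimuth_step_deg=40.0, max_range_km=100.0)
    grid, station = _grid_and_station()
    dbz = np.full((geo.n_az, geo.n_gates), 20.0)
    scan = make_scan({0.5: dbz}, geo, minutes_after_sunset=45.0)
    vpr = _delta_vpr(19)  # mass at 1950 m: far above the low beam at close range
    out = range_correct(scan, vpr, station, grid, "spring", 2019)
    r = geo.gate_centers_km()
    hc = beam_height(r, 0.5, station.antenna_height_m)
    w = np.exp(-((1950.0 - hc) ** 2) / (2.0 * beam_sd_m(r) ** 2))
    with np.errstate(divide="ignore"):
        factor = 1.0 / w
    dx, dy = geo.ground_offsets_km()
    for g in range(geo.n_gates):
        iy, ix = grid.pixel_index(station.x_km + dx[0, g], station.y_km + dy[0, g])
        defined = np.isfinite(out.values[iy, ix])
        should_be = factor[g] < 10.0 and 7.5 <= r[g] <= 80.0
        assert defined == should_be, f"gate {g} at {r[g]} km factor {factor[g]:.2f}"


def test_range_correct_all_zero_vpr_errors():
    geo = _series_geo()
    grid, station = _grid_and_station()
    scan = make_scan({0.5: np.zeros((geo.n_az, geo.n_gates))}, geo)
    zero_vpr = VPR(altitude_mid_m=(np.arange(20) + 0.5) * 100.0, density=np.zeros(20))
    with pytest.raises(ValueError):
        range_correct(scan, zero_vpr, station, grid, "spring", 2019)


# ---------------------------------------------------------------------------
# seasonal mean and mosaicking
# ---------------------------------------------------------------------------


def _raster(values, season="spring", year=2019, stations=("S1",)):
    grid = Grid(nx=2, ny=2)
    return StopoverRaster(
        values=np.asarray(values, dtype=float), grid=grid, season=season, year=year,
        provenance={"stations": list(stations), "nights": []},
    )


def test_seasonal_mean_single_night_is_identity():
    r = _raster([[1.0, 2.0], [np.nan, 4.0]])
    out = seasonal_station_raster([r])
    np.testing.assert_array_equal(out.values, r.values)


def test_seasonal_mean_averages_defined_nights_only():
    a = _raster([[2.0, np.nan], [2.0, np.nan]])
    b = _raster([[4.0, np.nan], [np.nan, np.nan]])
    c = _raster([[6.0, np.nan], [4.0, np.nan]])
    out = seasonal_station_raster([a, b, c]).values
    assert out[0, 0] == pytest.approx(4.0)  # mean of 2, 4, 6
    assert out[1, 0] == pytest.approx(3.0)  # defined 2 of 3 nights
    assert np.isnan(out[0, 1])


def test_seasonal_mean_rejects_mixed_seasons():
    with pytest.raises(ValueError):
        seasonal_station_raster([_raster([[1, 1], [1, 1]]), _raster([[1, 1], [1, 1]], season="fall")])


def test_mosaic_mean_and_union():
    a = _raster([[2.0, 5.0], [np.nan, np.nan]], stations=("S1",))
    b = _raster([[10.0, np.nan], [7.0, np.nan]], stations=("S2",))
    out = mosaic_stations([a, b])
    assert out.values[0, 0] == pytest.approx(6.0)  # overlap -> mean
    assert out.values[0, 1] == pytest.approx(5.0)  # disjoint -> original
    assert out.values[1, 0] == pytest.approx(7.0)
    assert np.isnan(out.values[1, 1])
    assert out.provenance["stations"] == ["S1", "S2"]


def test_mosaic_conserves_mass_where_single_station():
    rng = np.random.default_rng(1)
    vals = rng.uniform(1, 5, (2, 2))
    a = _raster(vals, stations=("S1",))
    b = _raster(np.full((2, 2), np.nan), stations=("S2",))
    out = mosaic_stations([a, b])
    assert np.nansum(out.values) == pytest.approx(vals.sum())


def test_empty_inputs_error():
    with pytest.raises(ValueError):
        seasonal_station_raster([])
    with pytest.raises(ValueError):
        mosaic_stations([])
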