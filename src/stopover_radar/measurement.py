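"""From cleaned nightly scans to seasonal 1-km stopover-density rasters.

Stages: median-reflectivity night curves, exodus-time selection via a
penalized GAM (smooth of minutes-after-sunset, per-date intercept offsets),
vertical-profile-of-reflectivity (VPR) range correction with a capped
adjustment factor, nightly scan selection, seasonal averaging, and
multi-station mosaicking.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np

from .config import MeasureConfig, StationSpec
from .grids import Grid
from .scans import FLAG_VALID, PolarScan, beam_height, beam_sd_m, dbz_to_linear

log = logging.getLogger(__name__)


@dataclass
class NightCurve:
    """Median linear reflectivity (eta, cm^2/km^3) through one night."""

    station_id: str
    night: dt.date
    minutes: np.ndarray
    median_eta: np.ndarray


@dataclass
class VPR:
    """Vertical profile of reflectivity: 20 bins of 100 m from 0 to 2000 m AGL."""

    altitude_mid_m: np.ndarray
    density: np.ndarray  # linear reflectivity per bin

    def __post_init__(self):
        if len(self.density) != len(self.altitude_mid_m):
            raise ValueError("bin mismatch")
        if np.any(self.density < 0):
            raise ValueError("VPR must be non-negative")


@dataclass
class StopoverRaster:
    """Vertically integrated reflectivity (cm^2/km^2) on the 1-km grid."""

    values: np.ndarray
    grid: Grid
    season: str
    year: int
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# night curves and exodus time
# ---------------------------------------------------------------------------


def median_reflectivity_series(
    scans: list[PolarScan], max_range_km: float = 100.0, eta_per_z: float = 1.0
) -> NightCurve:
    """Median eta of the lowest sweep out to ``max_range_km``, per scan."""
    if not scans:
        raise ValueError("no scans")
    station = scans[0].station_id
    night = scans[0].timestamp.date()
    minutes, medians = [], []
    for scan in sorted(scans, key=lambda s: s.timestamp):
        sw = scan.lowest
        r = scan.geometry.gate_centers_km()
        sel = (sw.flags == FLAG_VALID) & (r[None, :] <= max_range_km)
        vals = sw.dbz[sel]
        if vals.size == 0:
            continue
        minutes.append(scan.minutes_after_sunset)
        medians.append(float(np.median(dbz_to_linear(vals))) * eta_per_z)
    if not minutes:
        log.warning("all scans rejected for %s %s; empty night curve", station, night)
    return NightCurve(
        station_id=station,
        night=night,
        minutes=np.array(minutes, dtype=float),
        median_eta=np.array(medians, dtype=float),
    )


def fit_exodus_time(curves: list[NightCurve], basis_dim: int = 10) -> float:
    """Minutes after sunset with the greatest predicted rate of change in eta.

    A penalized B-spline smooth of median eta on minutes after sunset
    (basis dimension ``basis_dim``) with per-date intercept offsets; the
    smooth is evaluated on a 1-minute grid over [0, 150] and the left edge of
    the first finite difference's maximum is returned (ties -> earliest).
    """
    curves = [c for c in curves if len(c.minutes) >= 4]
    if len(curves) < 3:
        raise ValueError("need at least 3 nights with at least 4 samples each")
    minutes = np.concatenate([c.minutes for c in curves])
    eta = np.concatenate([c.median_eta for c in curves])
    dates = np.concatenate([[c.night.toordinal()] * len(c.minutes) for c in curves])

    sd = eta.std()
    if sd == 0:
        raise ValueError("no exodus signal: constant reflectivity series")
    y = (eta - eta.mean()) / sd

    from statsmodels.gam.api import BSplines, GLMGam

    bs = BSplines(minutes[:, None], df=[basis_dim], degree=[3], include_intercept=False)
    uniq = np.unique(dates)
    exog = np.ones((len(y), 1))
    if len(uniq) > 1:
        dummies = (dates[:, None] == uniq[None, 1:]).astype(float)
        exog = np.column_stack([exog, dummies])
    grid = np.arange(0.0, 150.0 + 1e-9, 1.0)
    exog_ref = np.tile(exog.mean(axis=0), (len(grid), 1))
    gam = GLMGam(y, exog=exog, smoother=bs, alpha=[1.0])
    try:
        alpha = gam.select_penweight(alphas=[np.logspace(-3, 3, 7)])[0]
        gam = GLMGam(y, exog=exog, smoother=bs, alpha=alpha)
    except Exception:  # keep the default penalty if selection fails
        pass
    try:
        res = gam.fit()
        pred = np.asarray(res.predict(exog=exog_ref, exog_smooth=grid[:, None]))
    except Exception:
        # degenerate (e.g. exactly interpolable) series: plain least squares
        # on the same design
        X = np.column_stack([exog, bs.basis])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        Xg = np.column_stack([exog_ref, bs.transform(grid[:, None])])
        pred = Xg @ beta
    diff = np.diff(pred)
    spread = pred.max() - pred.min()
    if spread < 1e-8:
        raise ValueError("no exodus signal: flat fitted curve")
    tol = 1e-9 * max(spread, 1.0)
    best = np.where(diff >= diff.max() - tol)[0][0]
    return float(grid[best])


def select_night_scan(
    scans: list[PolarScan], rejected: list[bool], exodus_min: float
) -> PolarScan | None:
    """The non-rejected scan nearest the exodus time; ties -> earlier."""
    candidates = [s for s, rej in zip(scans, rejected) if not rej]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda s: (abs(s.minutes_after_sunset - exodus_min), s.minutes_after_sunset),
    )


# ---------------------------------------------------------------------------
# VPR and range correction
# ---------------------------------------------------------------------------


def estimate_vpr(
    scan: PolarScan,
    antenna_height_m: float = 30.0,
    pool_range_km: tuple[float, float] = (5.0, 35.0),
    max_alt_m: float = 2000.0,
    bin_m: float = 100.0,
    eta_per_z: float = 1.0,
) -> VPR:
    """VPR by averaging valid eta per 100-m beam-center-height bin.

    Voxels are pooled over all sweeps and over ranges where every sweep still
    overlaps the 0-2000 m layer; empty bins are zero.
    """
    if len(scan.sweeps) < 2:
        raise ValueError("need at least 2 sweeps for a VPR")
    n_bins = int(round(max_alt_m / bin_m))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    r = scan.geometry.gate_centers_km()
    in_pool = (r >= pool_range_km[0]) & (r <= pool_range_km[1])
    for sw in scan.sweeps:
        heights = beam_height(r, sw.elevation_deg, antenna_height_m)
        bins = np.floor(heights / bin_m).astype(int)
        usable = in_pool & (bins >= 0) & (bins < n_bins)
        if not usable.any():
            continue
        valid = (sw.flags == FLAG_VALID) & usable[None, :]
        if not valid.any():
            continue
        eta = dbz_to_linear(sw.dbz) * eta_per_z
        for g in np.nonzero(usable)[0]:
            col_valid = valid[:, g]
            n = int(col_valid.sum())
            if n:
                sums[bins[g]] += float(eta[col_valid, g].sum())
                counts[bins[g]] += n
    if counts.sum() == 0:
        raise ValueError("no valid voxels in the VPR pooling range")
    density = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    mids = (np.arange(n_bins) + 0.5) * bin_m
    return VPR(altitude_mid_m=mids, density=density)


def range_correct(
    scan: PolarScan,
    vpr: VPR,
    station: StationSpec,
    grid: Grid,
    season: str,
    year: int,
    max_factor: float = 10.0,
    max_range_km: float = 80.0,
    min_range_km: float = 7.5,
    eta_per_z: float = 1.0,
    bin_depth_km: float = 0.1,
) -> StopoverRaster:
    """Range-corrected vertically integrated reflectivity on the 1-km grid.

    overlap(r) = sum_b VPR(b) w(b|r) / sum_b VPR(b), with w the Gaussian beam
    weight at the bin mid-height summed over the sweeps available at each
    voxel; the adjustment factor 1/overlap is capped (voxels with factor >=
    ``max_factor``, or outside [min_range, max_range], become missing).
    """
    total = vpr.density.sum()
    if total <= 0:
        raise ValueError("all-zero VPR")
    vprn = vpr.density / total
    geo = scan.geometry
    r = geo.gate_centers_km()
    sigma = beam_sd_m(r)

    col = np.zeros((geo.n_az, geo.n_gates))
    overlap = np.zeros((geo.n_az, geo.n_gates))
    any_valid = np.zeros((geo.n_az, geo.n_gates), dtype=bool)
    for sw in scan.sweeps:
        hc = beam_height(r, sw.elevation_deg, station.antenna_height_m)
        w = np.exp(-((vpr.altitude_mid_m[None, :] - hc[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2))
        v = w @ vprn  # (n_gates,)
        valid = sw.flags == FLAG_VALID
        eta = np.where(valid, dbz_to_linear(sw.dbz) * eta_per_z, 0.0)
        col += np.where(np.isfinite(eta), eta, 0.0)
        overlap += valid * v[None, :]
        any_valid |= valid

    with np.errstate(divide="ignore"):
        factor = np.where(overlap > 0, 1.0 / overlap, np.inf)
    ok = (
        any_valid
        & (factor < max_factor)
        & (r[None, :] >= min_range_km)
        & (r[None, :] <= max_range_km)
    )
    corrected = np.zeros_like(col)
    corrected[ok] = col[ok] * factor[ok] * bin_depth_km

    dx, dy = geo.ground_offsets_km()
    x = station.x_km + dx
    y = station.y_km + dy
    ok &= grid.contains(x, y)
    iy, ix = grid.pixel_index(x[ok], y[ok])
    flat = iy * grid.nx + ix
    sums = np.zeros(grid.ny * grid.nx)
    counts = np.zeros(grid.ny * grid.nx)
    np.add.at(sums, flat, corrected[ok])
    np.add.at(counts, flat, 1.0)
    values = np.full(grid.ny * grid.nx, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    return StopoverRaster(
        values=values.reshape(grid.shape),
        grid=grid,
        season=season,
        year=year,
        provenance={
            "stations": [station.station_id],
            "nights": [str(scan.timestamp.date())],
            "scan_time": scan.timestamp.isoformat(),
        },
    )


# ---------------------------------------------------------------------------
# seasonal aggregation and mosaicking
# ---------------------------------------------------------------------------


def _mean_where_defined(rasters: list[StopoverRaster]) -> np.ndarray:
    stack = np.stack([r.values for r in rasters])
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(stack).sum(axis=0)
        sums = np.nansum(stack, axis=0)
    out = np.full(stack.shape[1:], np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def seasonal_station_raster(nightly: list[StopoverRaster]) -> StopoverRaster:
    """Per-pixel mean over nights; missing only where missing every night."""
    if not nightly:
        raise ValueError("no nightly rasters")
    first = nightly[0]
    for r in nightly[1:]:
        if (r.season, r.year, r.grid) != (first.season, first.year, first.grid):
            raise ValueError("nightly rasters must share station/season/year and grid")
    nights = sorted({n for r in nightly for n in r.provenance.get("nights", [])})
    return StopoverRaster(
        values=_mean_where_defined(nightly),
        grid=first.grid,
        season=first.season,
        year=first.year,
        provenance={"stations": first.provenance.get("stations", []), "nights": nights},
    )


def mosaic_stations(rasters: list[StopoverRaster]) -> StopoverRaster:
    """Per-pixel mean across stations where coverage overlaps."""
    if not rasters:
        raise ValueError("no station rasters")
    first = rasters[0]
    for r in rasters[1:]:
        if (r.season, r.year, r.grid) != (first.season, first.year, first.grid):
            raise ValueError("station rasters must share season/year on a common grid")
    stations = sorted({s for r in rasters for s in r.provenance.get("stations", [])})
    nights = sorted({n for r in rasters for n in r.provenance.get("nights", [])})
    return StopoverRaster(
        values=_mean_where_defined(rasters),
        grid=first.grid,
        season=first.season,
        year=first.year,
        provenance={"stations": stations, "nights": nights},
    )


def measure_config_kwargs(cfg: MeasureConfig) -> dict:
    return {
        "max_factor": cfg.max_factor,
        "max_range_km": cfg.max_range_km,
        "min_range_km": cfg.min_range_km,
    }
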