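"""Polar scan data model, beam geometry, and clutter mitigation.

Implements the static quality-control chain applied to every station:
a topographic mask from beam geometry over terrain, a probability-of-detection
(POD) mask built from clear-condition winter scans, precipitation masking
with a ground-distance dilation and whole-scan rejection, and permanent
exclusion buffers (e.g. around bat roosts).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy.spatial import cKDTree

from .config import StationSpec
from .grids import Grid

log = logging.getLogger(__name__)

FLAG_VALID = 0
FLAG_MISSING = 1
FLAG_CLUTTER = 2
FLAG_PRECIP = 3

#: 4/3-earth effective radius for standard atmospheric refraction (km).
EFFECTIVE_EARTH_RADIUS_KM = 4.0 / 3.0 * 6371.0
#: Half-power beam width of the radar (degrees).
BEAMWIDTH_DEG = 1.0


@dataclass(frozen=True)
class PolarGeometry:
    """Polar sampling grid; defaults are the operational super-resolution."""

    gate_depth_m: float = 250.0
    azimuth_step_deg: float = 0.5
    max_range_km: float = 150.0

    @property
    def n_gates(self) -> int:
        return int(round(self.max_range_km * 1000.0 / self.gate_depth_m))

    @property
    def n_az(self) -> int:
        return int(round(360.0 / self.azimuth_step_deg))

    def gate_centers_km(self) -> np.ndarray:
        return (np.arange(self.n_gates) + 0.5) * self.gate_depth_m / 1000.0

    def az_centers_deg(self) -> np.ndarray:
        return (np.arange(self.n_az) + 0.5) * self.azimuth_step_deg

    def ground_offsets_km(self) -> tuple[np.ndarray, np.ndarray]:
        """(dx, dy) of voxel centers relative to the station, (n_az, n_gates)."""
        az = np.deg2rad(self.az_centers_deg())[:, None]
        r = self.gate_centers_km()[None, :]
        return r * np.sin(az), r * np.cos(az)


#: Fixed POD analysis grid: 1 degree x 500 m.
POD_AZ_STEP_DEG = 1.0
POD_GATE_DEPTH_M = 500.0


def pod_geometry(max_range_km: float = 150.0) -> PolarGeometry:
    return PolarGeometry(
        gate_depth_m=POD_GATE_DEPTH_M,
        azimuth_step_deg=POD_AZ_STEP_DEG,
        max_range_km=max_range_km,
    )


@dataclass
class Sweep:
    elevation_deg: float
    dbz: np.ndarray  # (n_az, n_gates) float32
    flags: np.ndarray  # uint8, same shape


@dataclass
class PolarScan:
    station_id: str
    timestamp: datetime
    geometry: PolarGeometry
    sweeps: list[Sweep]
    minutes_after_sunset: float | None = None
    truth: dict = field(default_factory=dict)  # simulator ground-truth masks

    def sweep(self, elevation_deg: float) -> Sweep:
        for s in self.sweeps:
            if abs(s.elevation_deg - elevation_deg) < 1e-6:
                return s
        raise KeyError(f"no sweep at {elevation_deg} deg")

    @property
    def lowest(self) -> Sweep:
        return min(self.sweeps, key=lambda s: s.elevation_deg)


@dataclass
class PolarMask:
    """Static boolean mask on a polar grid; True marks cells to remove.

    ``cells`` is (n_elevations, n_az, n_gates) when per-sweep, else
    (n_az, n_gates) applied to every sweep. Resampling between geometries is
    nearest-cell by voxel-center azimuth and range.
    """

    station_id: str
    geometry: PolarGeometry
    cells: np.ndarray
    elevations_deg: tuple[float, ...] | None = None

    def layer(self, elevation_deg: float) -> np.ndarray:
        if self.cells.ndim == 2:
            return self.cells
        if self.elevations_deg is None:
            raise ValueError("per-sweep mask without recorded elevations")
        idx = int(np.argmin(np.abs(np.array(self.elevations_deg) - elevation_deg)))
        return self.cells[idx]


def dbz_to_linear(dbz: np.ndarray) -> np.ndarray:
    return np.power(10.0, np.asarray(dbz, dtype=float) / 10.0)


def linear_to_dbz(z: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(np.asarray(z, dtype=float))


def beam_height(range_km, elevation_deg, antenna_height_m: float = 0.0):
    """Beam-center height (m) under 4/3-earth standard refraction.

    h = sqrt(r^2 + R'^2 + 2 r R' sin(theta)) - R' + h0, monotone increasing
    in both range and elevation.
    """
    r = np.asarray(range_km, dtype=float)
    if np.any(r < 0):
        raise ValueError("range must be non-negative")
    rp = EFFECTIVE_EARTH_RADIUS_KM
    theta = np.deg2rad(elevation_deg)
    h_km = np.sqrt(r**2 + rp**2 + 2.0 * r * rp * np.sin(theta)) - rp
    return h_km * 1000.0 + antenna_height_m


def beam_sd_m(range_km) -> np.ndarray:
    """Vertical sd (m) of the Gaussian beam power pattern at a given range."""
    fwhm_m = np.asarray(range_km, dtype=float) * 1000.0 * np.deg2rad(BEAMWIDTH_DEG)
    return np.maximum(fwhm_m / 2.355, 1.0)


def _resample_index(src: PolarGeometry, dst: PolarGeometry):
    """Indices of the dst cell containing each src voxel center."""
    az = np.minimum(
        (src.az_centers_deg() / dst.azimuth_step_deg).astype(int), dst.n_az - 1
    )
    gate = (src.gate_centers_km() * 1000.0 / dst.gate_depth_m).astype(int)
    return az, gate


def mask_on_geometry(mask: PolarMask, geometry: PolarGeometry, elevation_deg: float) -> np.ndarray:
    """Nearest-cell resample of a mask layer onto a scan geometry."""
    layer = mask.layer(elevation_deg)
    if mask.geometry == geometry:
        return layer
    az_idx, gate_idx = _resample_index(geometry, mask.geometry)
    inside = gate_idx < mask.geometry.n_gates
    out = np.zeros((geometry.n_az, geometry.n_gates), dtype=bool)
    gate_idx = np.minimum(gate_idx, mask.geometry.n_gates - 1)
    out[:] = layer[np.ix_(az_idx, gate_idx)]
    out[:, ~inside] = False
    return out


def apply_mask(scan: PolarScan, mask: PolarMask, flag: int = FLAG_MISSING) -> PolarScan:
    """Apply a static mask (idempotent): masked voxels become NaN + flagged."""
    for sw in scan.sweeps:
        cells = mask_on_geometry(mask, scan.geometry, sw.elevation_deg)
        sw.dbz[cells] = np.nan
        sw.flags[cells] = np.where(
            sw.flags[cells] == FLAG_VALID, np.uint8(flag), sw.flags[cells]
        )
    return scan


# ---------------------------------------------------------------------------
# topographic clutter
# ---------------------------------------------------------------------------


def topographic_clutter_mask(
    station: StationSpec,
    elevation_raster: np.ndarray,
    grid: Grid,
    geometry: PolarGeometry,
    elevations_deg: tuple[float, ...] | None = None,
) -> PolarMask:
    """Mask voxels whose lower beam edge is at or below terrain along the ray.

    The lower edge is the beam-center height minus half the 1-degree beam
    width; the criterion compares against the running maximum of terrain
    elevation out to each voxel's range (so gates unflag again once the beam
    climbs above an obstacle).
    """
    if not bool(grid.contains(station.x_km, station.y_km)):
        raise ValueError("station outside elevation raster")
    elevations_deg = elevations_deg or station.elevation_angles_deg
    dx, dy = geometry.ground_offsets_km()
    x = station.x_km + dx
    y = station.y_km + dy
    inside = grid.contains(x, y)
    iy, ix = grid.pixel_index(np.clip(x, grid.x0_km, grid.x0_km + grid.extent_km[0] - 1e-6),
                              np.clip(y, grid.y0_km, grid.y0_km + grid.extent_km[1] - 1e-6))
    terrain = np.where(inside, elevation_raster[iy, ix], -np.inf)
    running_max = np.maximum.accumulate(terrain, axis=1)

    siy, six = grid.pixel_index(station.x_km, station.y_km)
    antenna_asl = float(elevation_raster[siy, six]) + station.antenna_height_m
    r = geometry.gate_centers_km()
    half_width_m = r * 1000.0 * np.deg2rad(BEAMWIDTH_DEG) / 2.0

    cells = np.zeros((len(elevations_deg), geometry.n_az, geometry.n_gates), dtype=bool)
    for i, el in enumerate(elevations_deg):
        lower_edge = beam_height(r, el, antenna_asl) - half_width_m
        cells[i] = lower_edge[None, :] <= running_max
    return PolarMask(
        station_id=station.station_id,
        geometry=geometry,
        cells=cells,
        elevations_deg=tuple(elevations_deg),
    )


# ---------------------------------------------------------------------------
# POD clutter
# ---------------------------------------------------------------------------


def scan_on_pod_grid(scan: PolarScan) -> dict[float, np.ndarray]:
    """Per-sweep dBZ on the fixed 1-deg x 500-m POD grid (block mean of Z)."""
    geo = scan.geometry
    pod_geo = pod_geometry(min(150.0, geo.max_range_km))
    if (
        geo.azimuth_step_deg == pod_geo.azimuth_step_deg
        and geo.gate_depth_m == pod_geo.gate_depth_m
        and geo.max_range_km <= pod_geo.max_range_km
    ):  # scan already on the POD grid
        return {sw.elevation_deg: sw.dbz for sw in scan.sweeps}
    az_idx, gate_idx = _resample_index(geo, pod_geo)
    out = {}
    for sw in scan.sweeps:
        z = dbz_to_linear(sw.dbz)
        z = np.where(np.isfinite(z), z, 0.0)
        acc = np.zeros((pod_geo.n_az, pod_geo.n_gates))
        cnt = np.zeros_like(acc)
        np.add.at(acc, (az_idx[:, None], gate_idx[None, :]), z)
        np.add.at(cnt, (az_idx[:, None], gate_idx[None, :]), 1.0)
        mean = np.full(acc.shape, np.nan)
        np.divide(acc, cnt, out=mean, where=cnt > 0)
        out[sw.elevation_deg] = linear_to_dbz(mean)
    return out


def select_clear_scans(
    scans: list[PolarScan],
    n_pool: int = 300,
    n_select: int = 30,
    clip_dbz: float = 35.0,
) -> list[PolarScan]:
    """Pick the ``n_select`` scans with the lowest total linear reflectivity.

    Reflectivity is clipped to a ceiling (35 dBZ) and totalled over the POD
    grid; ties break toward the earlier timestamp.
    """
    pool = sorted(scans, key=lambda s: s.timestamp)[:n_pool]
    if len(pool) < n_select:
        raise ValueError(f"need at least {n_select} scans, got {len(pool)}")
    totals = []
    for scan in pool:
        tot = 0.0
        for dbz in scan_on_pod_grid(scan).values():
            z = dbz_to_linear(np.minimum(dbz, clip_dbz))
            tot += float(np.nansum(z))
        totals.append(tot)
    order = sorted(range(len(pool)), key=lambda i: (totals[i], pool[i].timestamp))
    return [pool[i] for i in order[:n_select]]


def pod_clutter_mask(
    clear_scans_by_year: dict[int, list[PolarScan]],
    pod_dbz: float = 10.0,
    pod_frac: float = 0.20,
    min_years: int = 2,
) -> PolarMask:
    """Static clutter mask from multi-year probability of detection.

    Per year and POD-grid cell, POD is the fraction of clear scans whose
    reflectivity strictly exceeds ``pod_dbz``; a cell is clutter iff
    POD >= ``pod_frac`` in at least ``min_years`` years.
    """
    years = sorted(clear_scans_by_year)
    if not years:
        raise ValueError("need at least one year of clear scans")
    exceed_years = None
    station_id = None
    elevations: tuple[float, ...] | None = None
    pod_geo = None
    for year in years:
        scans = clear_scans_by_year[year]
        if not scans:
            log.warning("no clear scans for year %s; skipped", year)
            continue
        station_id = scans[0].station_id
        elevations = tuple(sw.elevation_deg for sw in scans[0].sweeps)
        counts = None
        for scan in scans:
            grids = scan_on_pod_grid(scan)
            if pod_geo is None:
                pod_geo = pod_geometry(min(150.0, scan.geometry.max_range_km))
            stackd = np.stack([grids[el] for el in elevations])
            hit = (stackd > pod_dbz) & np.isfinite(stackd)
            counts = hit.astype(np.int64) if counts is None else counts + hit
        pod = counts / len(scans)
        year_flag = pod >= pod_frac
        exceed_years = year_flag.astype(np.int64) if exceed_years is None else exceed_years + year_flag
    if exceed_years is None:
        raise ValueError("no usable clear scans in any year")
    cells = exceed_years >= min_years
    return PolarMask(
        station_id=station_id, geometry=pod_geo, cells=cells, elevations_deg=elevations
    )


# ---------------------------------------------------------------------------
# precipitation
# ---------------------------------------------------------------------------


def apply_precipitation_mask(
    scan: PolarScan,
    precip_mask: PolarMask,
    dilate_km: float = 5.0,
    reject_frac: float = 0.30,
    eval_range_km: tuple[float, float] = (7.5, 80.0),
) -> tuple[PolarScan, bool]:
    """Remove precipitation voxels plus a ground-distance dilation buffer.

    All voxels within ``dilate_km`` Euclidean ground distance of a
    precipitation voxel become missing. The scan is rejected when the
    contaminated fraction of the evaluated annulus strictly exceeds
    ``reject_frac``.
    """
    if precip_mask.geometry != scan.geometry:
        raise ValueError("precipitation mask geometry must match the scan")
    cells = precip_mask.cells if precip_mask.cells.ndim == 2 else precip_mask.cells.any(axis=0)
    geo = scan.geometry
    if cells.any():
        dx, dy = geo.ground_offsets_km()
        pts = np.column_stack([dx[cells], dy[cells]])
        tree = cKDTree(pts)
        dist, _ = tree.query(np.column_stack([dx.ravel(), dy.ravel()]), k=1)
        contaminated = (dist <= dilate_km).reshape(cells.shape)
    else:
        contaminated = np.zeros(cells.shape, dtype=bool)

    for sw in scan.sweeps:
        sw.dbz[contaminated] = np.nan
        sw.flags[contaminated] = np.where(
            sw.flags[contaminated] == FLAG_VALID, np.uint8(FLAG_PRECIP), sw.flags[contaminated]
        )

    r = geo.gate_centers_km()
    annulus = (r >= eval_range_km[0]) & (r < eval_range_km[1])
    frac = float(contaminated[:, annulus].mean()) if annulus.any() else 0.0
    return scan, frac > reject_frac


def exclusion_mask(
    station: StationSpec,
    geometry: PolarGeometry,
    buffers: tuple[tuple[float, float, float], ...],
) -> PolarMask:
    """Permanent circular exclusion buffers (e.g. bat roosts), domain coords."""
    dx, dy = geometry.ground_offsets_km()
    x = station.x_km + dx
    y = station.y_km + dy
    cells = np.zeros(dx.shape, dtype=bool)
    for bx, by, radius in buffers:
        cells |= np.hypot(x - bx, y - by) <= radius
    return PolarMask(station_id=station.station_id, geometry=geometry, cells=cells)
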