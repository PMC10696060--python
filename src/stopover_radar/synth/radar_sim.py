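"""Forward simulator of nightly radar scan series over a known density field.

Airborne reflectivity above each ground pixel follows a logistic take-off
curve after sunset (station-specific midpoint) times the local truth stopover
density, distributed over altitude by a fixed vertical profile. Each voxel
records the Gaussian-beam-weighted sample of that column as dBZ, with
multiplicative voxel noise, a noise floor, and injected contamination
(persistent ground clutter, drifting precipitation cells, optional bat
rings) whose ground-truth masks ride along with every scan.
"""
from __future__ import annotations

import datetime as dt

import numpy as np
from scipy import stats

from ..config import (
    LandscapeConfig,
    PipelineConfig,
    RadarSimConfig,
    SEASON_WINDOWS,
    StationSpec,
    rng_for,
)
from ..grids import Grid
from ..scans import (
    FLAG_MISSING,
    FLAG_VALID,
    PolarGeometry,
    PolarScan,
    Sweep,
    beam_height,
    beam_sd_m,
)

SUNSET_LOCAL = dt.time(19, 0)


def vertical_profile(cfg: RadarSimConfig, max_alt_m: float = 2000.0, bin_m: float = 100.0):
    """Fraction of birds per altitude bin: truncated normal on [0, max]."""
    edges = np.arange(0.0, max_alt_m + bin_m, bin_m)
    lo, hi = edges[:-1], edges[1:]
    cdf = stats.norm.cdf
    mass = cdf(hi, cfg.profile_mean_m, cfg.profile_sd_m) - cdf(lo, cfg.profile_mean_m, cfg.profile_sd_m)
    mass /= mass.sum()
    mids = (lo + hi) / 2.0
    return mids, mass


class SimWorld:
    """Bundles the landscape grid, truth densities and simulator geometry."""

    def __init__(
        self,
        grid: Grid,
        landscape_config: LandscapeConfig,
        truth_density: dict[tuple[str, int], np.ndarray],
        stations: list[StationSpec],
        geometry: PolarGeometry,
        sim: RadarSimConfig,
        seed: int,
        elevation: np.ndarray | None = None,
    ):
        self.grid = grid
        self.landscape_config = landscape_config
        self.truth_density = truth_density
        self.stations = {s.station_id: s for s in stations}
        self.geometry = geometry
        self.sim = sim
        self.seed = seed
        self.elevation = elevation
        self._cache: dict[str, dict] = {}

    @classmethod
    def from_config(cls, cfg: PipelineConfig, stack, truth_density, stations) -> "SimWorld":
        geometry = PolarGeometry(
            gate_depth_m=cfg.gate_depth_m,
            azimuth_step_deg=cfg.azimuth_step_deg,
            max_range_km=cfg.scan_max_range_km,
        )
        return cls(
            grid=stack.grid,
            landscape_config=cfg.landscape,
            truth_density=truth_density,
            stations=stations,
            geometry=geometry,
            sim=cfg.radar_sim,
            seed=cfg.seed,
            elevation=stack.layers.get("elevation"),
        )

    # -- per-station precomputation ----------------------------------------

    def _station_geom(self, station: StationSpec) -> dict:
        cached = self._cache.get(station.station_id)
        if cached is not None:
            return cached
        geo = self.geometry
        dx, dy = geo.ground_offsets_km()
        x = station.x_km + dx
        y = station.y_km + dy
        inside = self.grid.contains(x, y)
        iy, ix = self.grid.pixel_index(
            np.clip(x, 0, self.grid.extent_km[0] - 1e-6),
            np.clip(y, 0, self.grid.extent_km[1] - 1e-6),
        )
        flat = np.where(inside, iy * self.grid.nx + ix, 0)

        mids, mass = vertical_profile(self.sim)
        r = geo.gate_centers_km()
        sigma = beam_sd_m(r)  # (n_gates,)
        coupling = np.empty((len(station.elevation_angles_deg), geo.n_gates))
        for i, el in enumerate(station.elevation_angles_deg):
            hc = beam_height(r, el, station.antenna_height_m)
            w = np.exp(-((mids[None, :] - hc[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2))
            coupling[i] = w @ (mass / 0.1)  # bins are 0.1 km deep
        # persistent ground clutter on the two lowest sweeps
        rng = rng_for(self.seed, "clutter", station.station_id)
        clutter = rng.random((geo.n_az, geo.n_gates)) < self.sim.clutter_frac
        with np.errstate(divide="ignore"):
            coupling_db = 10.0 * np.log10(coupling)
        geom = {
            "flat": flat,
            "inside": inside,
            "coupling": coupling,
            "coupling_db": coupling_db.astype(np.float32),
            "dx": dx,
            "dy": dy,
            "clutter": clutter,
        }
        self._cache[station.station_id] = geom
        return geom

    def _density_db(self, season: str, year: int, sid: str) -> np.ndarray:
        """10 log10 of truth density sampled onto the polar grid (NaN outside)."""
        key = ("ddb", season, year, sid)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        geom = self._station_geom(self.stations[sid])
        density = self.truth_density[(season, year)].ravel()
        d_vox = np.where(geom["inside"], density[geom["flat"]], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ddb = 10.0 * np.log10(d_vox)
        self._cache[key] = ddb.astype(np.float32)
        return self._cache[key]

    def takeoff_midpoint_min(self, station_id: str) -> float:
        lo, hi = self.sim.takeoff_midpoint_range_min
        return float(rng_for(self.seed, "t0", station_id).uniform(lo, hi))

    def clutter_truth(self, station_id: str) -> np.ndarray:
        return self._station_geom(self.stations[station_id])["clutter"]

    # -- nightly scans ------------------------------------------------------

    def scan_times(self) -> np.ndarray:
        return np.arange(0.0, self.sim.window_min + 1e-9, self.sim.scan_interval_min)

    def _night_precip(self, station: StationSpec, night: dt.date):
        """Drifting precipitation cell for this station-night, or None."""
        rng = rng_for(self.seed, "precip", station.station_id, night)
        if rng.random() >= self.sim.precip_prob_per_night:
            return None
        heavy = rng.random() < self.sim.heavy_precip_prob
        radius = rng.uniform(40.0, 70.0) if heavy else rng.uniform(5.0, 25.0)
        rc = rng.uniform(0.0, 80.0)
        theta = rng.uniform(0.0, 2 * np.pi)
        cx, cy = rc * np.cos(theta), rc * np.sin(theta)
        vx, vy = rng.normal(0.0, 0.15, 2)  # km per minute
        return {"cx": cx, "cy": cy, "vx": vx, "vy": vy, "radius": radius}

    def simulate_station_scans(
        self,
        station_id: str,
        season: str,
        year: int,
        night: dt.date,
        scan_indices: list[int] | None = None,
    ) -> list[PolarScan]:
        """One scan every ``scan_interval_min`` from sunset to sunset+150 min.

        ``scan_indices`` regenerates a subset of the night's scans; per-scan
        random streams are keyed by scan index, so a subset is bit-identical
        to the corresponding members of the full series.
        """
        (m0, d0), (m1, d1) = SEASON_WINDOWS[season]
        if not (dt.date(year, m0, d0) <= night <= dt.date(year, m1, d1)):
            raise ValueError(f"night {night} outside the {season} {year} window")
        station = self.stations[station_id]
        geom = self._station_geom(station)
        ddb = self._density_db(season, year, station_id)

        t0 = self.takeoff_midpoint_min(station_id)
        rng_night = rng_for(self.seed, "night", station_id, night)
        night_factor = float(
            np.exp(rng_night.normal(-0.5 * self.sim.night_sd_log**2, self.sim.night_sd_log))
        )
        precip = self._night_precip(station, night)
        bats = None
        if self.sim.bat_rings:
            rng_b = rng_for(self.seed, "bats", station_id, night)
            if rng_b.random() < 0.5:
                rc = rng_b.uniform(10.0, 50.0)
                th = rng_b.uniform(0.0, 2 * np.pi)
                bats = {"cx": rc * np.cos(th), "cy": rc * np.sin(th), "start": rng_b.uniform(0, 30)}

        # multiplicative lognormal voxel noise, expressed additively in dB
        # with a mean offset so the linear-domain noise is unbiased
        sd_db = self.sim.voxel_noise_sd_log * 10.0 / np.log(10.0)
        mean_db = -0.5 * self.sim.voxel_noise_sd_log**2 * 10.0 / np.log(10.0)
        eta_db_off = -10.0 * np.log10(self.sim.eta_per_z)  # eta -> Z scale
        floor = np.float32(self.sim.noise_floor_dbz)
        scans = []
        for k, t in enumerate(self.scan_times()):
            if scan_indices is not None and k not in scan_indices:
                continue
            rng_scan = rng_for(self.seed, "scan", station_id, night, k)
            frac_airborne = 1.0 / (1.0 + np.exp(-(t - t0) / self.sim.takeoff_scale_min))
            with np.errstate(divide="ignore"):
                f_db = 10.0 * np.log10(frac_airborne * night_factor)
            sweeps = []
            precip_cells = np.zeros(ddb.shape, dtype=bool)
            if precip is not None:
                px = precip["cx"] + precip["vx"] * t
                py = precip["cy"] + precip["vy"] * t
                precip_cells = (
                    np.hypot(geom["dx"] - px, geom["dy"] - py) <= precip["radius"]
                )
            bat_cells = np.zeros(ddb.shape, dtype=bool)
            if bats is not None and t >= bats["start"]:
                ring_r = 1.0 * (t - bats["start"]) + 2.0
                d = np.hypot(geom["dx"] - bats["cx"], geom["dy"] - bats["cy"])
                bat_cells = np.abs(d - ring_r) <= 1.5
            for i, el in enumerate(station.elevation_angles_deg):
                noise = rng_scan.standard_normal(ddb.shape, dtype=np.float32)
                dbz = ddb + geom["coupling_db"][i][None, :] + np.float32(f_db + eta_db_off + mean_db)
                dbz += sd_db * noise
                dbz = np.maximum(dbz, floor)  # NaN outside the domain propagates
                if i < 2:  # ground clutter contaminates the low sweeps
                    dbz[geom["clutter"]] = self.sim.clutter_dbz + rng_scan.normal(
                        0.0, 1.5, int(geom["clutter"].sum())
                    )
                if precip_cells.any():
                    dbz[precip_cells] = self.sim.precip_dbz + rng_scan.normal(
                        0.0, 2.0, int(precip_cells.sum())
                    )
                if bat_cells.any() and i < 3:
                    dbz[bat_cells] = 28.0 + rng_scan.normal(0.0, 2.0, int(bat_cells.sum()))
                flags = np.where(np.isfinite(dbz), FLAG_VALID, FLAG_MISSING).astype(np.uint8)
                sweeps.append(Sweep(elevation_deg=el, dbz=dbz.astype(np.float32), flags=flags))
            ts = dt.datetime.combine(night, SUNSET_LOCAL) + dt.timedelta(minutes=float(t))
            scans.append(
                PolarScan(
                    station_id=station_id,
                    timestamp=ts,
                    geometry=self.geometry,
                    sweeps=sweeps,
                    minutes_after_sunset=float(t),
                    truth={
                        "clutter": geom["clutter"],
                        "precip": precip_cells,
                        "bats": bat_cells,
                    },
                )
            )
        return scans

    # -- winter clear-condition pool ----------------------------------------

    def simulate_winter_scans(self, station_id: str, year: int, n_scans: int) -> list[PolarScan]:
        """January scans: noise floor + persistent clutter + occasional weather."""
        station = self.stations[station_id]
        geom = self._station_geom(station)
        scans = []
        for k in range(n_scans):
            rng = rng_for(self.seed, "winter", station_id, year, k)
            sweeps = []
            weather = rng.random() < self.sim.winter_weather_prob
            if weather:
                wx, wy = rng.uniform(-60, 60, 2)
                wr = rng.uniform(30.0, 90.0)
                wcells = np.hypot(geom["dx"] - wx, geom["dy"] - wy) <= wr
            for i, el in enumerate(station.elevation_angles_deg):
                dbz = self.sim.noise_floor_dbz + 1.3 * rng.standard_normal(
                    geom["dx"].shape, dtype=np.float32
                )
                if weather:
                    dbz[wcells] = 20.0 + rng.normal(0.0, 3.0, int(wcells.sum()))
                if i < 2:
                    dbz[geom["clutter"]] = self.sim.clutter_dbz + rng.normal(
                        0.0, 1.5, int(geom["clutter"].sum())
                    )
                dbz[~geom["inside"]] = np.nan
                flags = np.where(np.isfinite(dbz), FLAG_VALID, FLAG_MISSING).astype(np.uint8)
                sweeps.append(Sweep(elevation_deg=el, dbz=dbz.astype(np.float32), flags=flags))
            ts = dt.datetime(year, 1, 2) + dt.timedelta(minutes=10.0 * k)
            scans.append(
                PolarScan(
                    station_id=station_id,
                    timestamp=ts,
                    geometry=self.geometry,
                    sweeps=sweeps,
                    truth={"clutter": geom["clutter"]},
                )
            )
        return scans


def sampled_nights(cfg: PipelineConfig, season: str, year: int) -> list[dt.date]:
    """The nights simulated at desk scale: evenly spread over the window."""
    from ..config import sample_nights

    return sample_nights(year, season, cfg.nights_per_season_year)
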