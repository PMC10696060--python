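"""End-to-end orchestration of the synthetic stopover analysis.

Stages: synthetic world -> clutter masks -> nightly measurement (exodus
selection + range correction) -> seasonal mosaics -> predictor table ->
partitioned training -> holdout experiment -> interpretation -> maps.
Each stage is an importable function; :func:`run_pipeline` chains them and
optionally writes products with provenance.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import (
    PipelineConfig,
    StationSpec,
    default_stations,
    season_nights,
)
from .interpret import category_gain_summary, mean_gain
from .measurement import (
    StopoverRaster,
    estimate_vpr,
    fit_exodus_time,
    median_reflectivity_series,
    mosaic_stations,
    range_correct,
    seasonal_station_raster,
)
from .model import (
    evaluate_holdout,
    holdout_experiment,
    location_split,
    spatial_partition,
    train_partition,
)
from .predictors import add_andd_layers, assemble_training_table, predictor_registry
from .scans import (
    PolarMask,
    apply_mask,
    apply_precipitation_mask,
    exclusion_mask,
    pod_clutter_mask,
    select_clear_scans,
    topographic_clutter_mask,
)
from .synth.landscape import generate_landscape
from .synth.radar_sim import SimWorld, sampled_nights
from .synth.truth import generate_truth_density

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------


def validate_config(cfg: PipelineConfig) -> list[tuple[str, str]]:
    """Return (level, message) findings; empty iff the config is runnable."""
    findings: list[tuple[str, str]] = []
    w, h = cfg.landscape.domain_size_km
    if cfg.truth.spatial_noise_sd < 0 or cfg.truth.obs_noise_sd < 0:
        findings.append(("error", "negative noise sd in truth model"))
    for season in cfg.landscape.seasons:
        n = len(season_nights(cfg.landscape.years[0], season))
        if n != 93:
            findings.append(("error", f"{season} window has {n} nights, expected 93"))
    for side in (cfg.partition.side_small_km, cfg.partition.side_large_km):
        if side > max(w, h):
            findings.append(("warning", f"box side {side} km exceeds domain; box clipped to domain"))
    if cfg.n_points <= 0:
        findings.append(("error", "n_points must be positive"))
    if cfg.nights_per_season_year < 3:
        findings.append(("error", "need at least 3 nights per season-year for exodus fitting"))
    for st in default_stations(cfg.landscape):
        if not (0 <= st.x_km <= w and 0 <= st.y_km <= h):
            findings.append(("error", f"station {st.station_id} outside domain"))
    return findings


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def build_world(cfg: PipelineConfig):
    """Landscape, ANDD layers, stations, truth densities, radar simulator."""
    stack = generate_landscape(cfg.landscape, cfg.seed)
    add_andd_layers(stack)
    stations = default_stations(cfg.landscape)
    truth = {
        (season, year): generate_truth_density(stack, cfg.truth, season, year, cfg.seed)
        for season in cfg.landscape.seasons
        for year in cfg.landscape.years
    }
    world = SimWorld.from_config(cfg, stack, truth, stations)
    return stack, stations, truth, world


def station_quality_masks(world: SimWorld, cfg: PipelineConfig) -> dict[str, list[PolarMask]]:
    """Static topographic + POD clutter masks (plus exclusion buffers)."""
    masks: dict[str, list[PolarMask]] = {}
    for sid, station in world.stations.items():
        if sid in cfg.clutter.excluded_stations:
            continue
        station_masks = []
        if world.elevation is not None:
            station_masks.append(
                topographic_clutter_mask(station, world.elevation, world.grid, world.geometry)
            )
        clear = {}
        for year in cfg.landscape.years:
            pool = world.simulate_winter_scans(sid, year, cfg.clutter.n_pool)
            clear[year] = select_clear_scans(
                pool, cfg.clutter.n_pool, cfg.clutter.n_select, cfg.clutter.clip_dbz
            )
        station_masks.append(
            pod_clutter_mask(
                clear, cfg.clutter.pod_dbz, cfg.clutter.pod_frac, cfg.clutter.min_years
            )
        )
        if cfg.clutter.bat_buffers:
            station_masks.append(
                exclusion_mask(station, world.geometry, cfg.clutter.bat_buffers)
            )
        masks[sid] = station_masks
    return masks


def _masked_night(world, cfg, masks, sid, season, year, night, scan_indices=None):
    """Simulate one night, apply static masks and precipitation screening."""
    scans = world.simulate_station_scans(sid, season, year, night, scan_indices)
    rejected = []
    for scan in scans:
        for mask in masks[sid]:
            apply_mask(scan, mask)
        precip_mask = PolarMask(
            station_id=sid, geometry=scan.geometry, cells=scan.truth["precip"]
        )
        _, rej = apply_precipitation_mask(
            scan,
            precip_mask,
            cfg.clutter.dilate_km,
            cfg.clutter.reject_frac,
            cfg.clutter.eval_range_km,
        )
        rejected.append(rej)
    return scans, rejected


def measure_season(
    world: SimWorld, cfg: PipelineConfig, masks: dict[str, list[PolarMask]], season: str
):
    """Seasonal measured stopover mosaics per year, plus provenance.

    Two passes per station: night curves for the exodus GAM first (recording
    which scans survive precipitation screening), then only the selected
    scan of each night is regenerated, VPR-estimated and range-corrected.
    """
    eta_per_z = world.sim.eta_per_z
    mcfg = cfg.measure
    nightly_by_year: dict[int, dict[str, list[StopoverRaster]]] = {
        y: {} for y in cfg.landscape.years
    }
    exodus_by_station: dict[str, float] = {}
    prov_rows = []
    for sid, station in world.stations.items():
        if sid not in masks:
            continue
        curves = []
        night_record: dict[tuple[int, str], tuple[list[float], list[bool]]] = {}
        for year in cfg.landscape.years:
            for night in sampled_nights(cfg, season, year):
                scans, rejected = _masked_night(world, cfg, masks, sid, season, year, night)
                keep = [s for s, r in zip(scans, rejected) if not r]
                if keep:
                    curves.append(
                        median_reflectivity_series(keep, mcfg.exodus_max_range_km, eta_per_z)
                    )
                night_record[(year, str(night))] = (
                    [s.minutes_after_sunset for s in scans],
                    rejected,
                )
        exodus = fit_exodus_time(curves, cfg.measure.exodus_basis_dim)
        exodus_by_station[sid] = exodus
        for year in cfg.landscape.years:
            rasters = []
            for night in sampled_nights(cfg, season, year):
                minutes, rejected = night_record[(year, str(night))]
                candidates = [
                    (abs(m - exodus), m, i)
                    for i, (m, rej) in enumerate(zip(minutes, rejected))
                    if not rej
                ]
                if candidates:
                    sel = min(candidates)[2]
                    scans, _ = _masked_night(
                        world, cfg, masks, sid, season, year, night, scan_indices=[sel]
                    )
                    scan = scans[0]
                else:
                    scan = None
                if scan is None:
                    prov_rows.append(
                        {"station": sid, "season": season, "year": year,
                         "night": str(night), "chosen_scan": None, "all_rejected": True}
                    )
                    continue
                try:
                    vpr = estimate_vpr(
                        scan,
                        station.antenna_height_m,
                        mcfg.vpr_range_km,
                        mcfg.vpr_max_alt_m,
                        mcfg.vpr_bin_m,
                        eta_per_z,
                    )
                except ValueError:
                    continue
                rasters.append(
                    range_correct(
                        scan, vpr, station, world.grid, season, year,
                        mcfg.max_factor, mcfg.max_range_km, mcfg.min_range_km, eta_per_z,
                    )
                )
                prov_rows.append(
                    {"station": sid, "season": season, "year": year, "night": str(night),
                     "chosen_scan": scan.timestamp.isoformat(), "all_rejected": False}
                )
            if rasters:
                nightly_by_year[year].setdefault(sid, []).extend(rasters)
    mosaics = {}
    for year in cfg.landscape.years:
        per_station = [
            seasonal_station_raster(r) for r in nightly_by_year[year].values() if r
        ]
        mosaics[year] = mosaic_stations(per_station)
    return mosaics, pd.DataFrame(prov_rows), exodus_by_station


def season_table(
    cfg: PipelineConfig,
    stack,
    stations: list[StationSpec],
    mosaics: dict[int, StopoverRaster],
    season: str,
) -> pd.DataFrame:
    """Training table with the global location-level split attached."""
    table = assemble_training_table(
        mosaics, stack, season, cfg.n_points, cfg.seed, stations
    )
    table["split"] = location_split(
        table["loc_id"].to_numpy(), cfg.seed, cfg.boost.split_fractions
    )
    return table


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
    seasons: tuple[str, ...] | None = None,
    train_standard: bool = True,
    run_holdout: bool = True,
    interpret: bool = True,
) -> dict:
    """Execute the full analysis; returns a product dictionary.

    Idempotent for a fixed config + seed: all randomness is derived from
    ``cfg.seed``.
    """
    findings = validate_config(cfg)
    errors = [m for lvl, m in findings if lvl == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))

    products: dict = {"config": cfg, "findings": findings}
    stack, stations, truth, world = build_world(cfg)
    products.update(stack=stack, stations=stations, truth=truth, world=world)
    masks = station_quality_masks(world, cfg)
    products["masks"] = masks

    boxes = spatial_partition(
        cfg.landscape.domain_size_km,
        cfg.partition.n_small,
        cfg.partition.n_large,
        cfg.partition.side_small_km,
        cfg.partition.side_large_km,
        cfg.seed,
    )
    products["boxes"] = boxes
    small_boxes = [b for b in boxes if b.side_km == cfg.partition.side_small_km]

    for season in seasons or cfg.landscape.seasons:
        try:
            mosaics, provenance, exodus = measure_season(world, cfg, masks, season)
        except Exception as exc:
            raise RuntimeError(f"stage 'measure' failed for season {season}: {exc}") from exc
        table = season_table(cfg, stack, stations, mosaics, season)
        entry = {
            "mosaics": mosaics,
            "provenance": provenance,
            "exodus_min": exodus,
            "table": table,
        }
        if train_standard:
            entry["models"] = train_partition(
                table, small_boxes, cfg.boost, cfg.partition.min_rows
            )
            if interpret:
                gains = mean_gain(entry["models"])
                entry["mean_gain"] = gains
                entry["category_gain"] = category_gain_summary(gains, predictor_registry())
        if run_holdout:
            pool = holdout_experiment(
                table, small_boxes, cfg.holdout, cfg.boost
            )
            entry["holdout_pool"] = pool
            entry["holdout"] = evaluate_holdout(pool, cfg.seed) if len(pool) else None
        products[season] = entry

    if outdir is not None:
        _write_products(cfg, products, Path(outdir))
    return products


def _write_products(cfg: PipelineConfig, products: dict, outdir: Path) -> None:
    from .io import save_raster, save_table, write_provenance

    outdir.mkdir(parents=True, exist_ok=True)
    for season in cfg.landscape.seasons:
        if season not in products:
            continue
        entry = products[season]
        for year, raster in entry["mosaics"].items():
            save_raster(
                outdir / f"measured_{season}_{year}.tif", raster.values, raster.grid,
                meta={"season": season, "year": year},
            )
        save_table(outdir / f"table_{season}.csv", entry["table"], predictor_registry())
        entry["provenance"].to_csv(outdir / f"scan_provenance_{season}.csv", index=False)
        if entry.get("holdout"):
            pd.Series(entry["holdout"]).to_json(outdir / f"holdout_{season}.json")
    write_provenance(outdir / "provenance.json", cfg, cfg.seed)
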