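"""The 49-predictor table: thermal time, EVI, land cover, and assembly.

Predictor registry (49 columns): 4 monthly EVI, 15 land-cover fractions at
1-km, 15 at 5-km, percent canopy, percent impervious, 8 semimonthly
accumulated nocturnal degree-day (ANDD) layers, seasonal precipitation,
skyglow, elevation, distance to radar, and year.
"""
from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .config import LANDCOVER_CLASSES, NLCD_CODE_TO_CLASS, SEASON_MONTHS, StationSpec, rng_for
from .grids import focal_mean
from .measurement import StopoverRaster
from .stack import LSTSeries, PredictorStack

log = logging.getLogger(__name__)

T_BASE_C = 0.0


def predictor_columns() -> list[str]:
    cols = [f"evi_m{m}" for m in range(1, 5)]
    cols += [f"lc1_{c}" for c in LANDCOVER_CLASSES]
    cols += [f"lc5_{c}" for c in LANDCOVER_CLASSES]
    cols += ["canopy", "impervious"]
    cols += [f"andd_h{h}" for h in range(1, 9)]
    cols += ["precip", "skyglow", "elevation", "distance_to_radar_km", "year"]
    return cols


def predictor_registry() -> dict[str, str]:
    """Column -> category map (used for category-level gain pooling)."""
    reg = {}
    for c in predictor_columns():
        if c.startswith("evi_"):
            reg[c] = "evi"
        elif c.startswith("lc1_"):
            reg[c] = "landcover_1km"
        elif c.startswith("lc5_"):
            reg[c] = "landcover_5km"
        elif c.startswith("andd_"):
            reg[c] = "andd"
        elif c == "canopy":
            reg[c] = "canopy"
        elif c == "impervious":
            reg[c] = "impervious"
        elif c == "precip":
            reg[c] = "precipitation"
        elif c == "distance_to_radar_km":
            reg[c] = "distance_to_radar"
        else:
            reg[c] = c
    return reg


# ---------------------------------------------------------------------------
# minimum nightly LST and gap filling
# ---------------------------------------------------------------------------


def min_nightly_lst(series: LSTSeries) -> np.ndarray:
    """Per-composite minimum of the two platform overpasses.

    One platform missing -> the other; both missing -> missing.
    """
    a, b = series.lst_2230, series.lst_0130
    out = np.where(np.isnan(a), b, np.where(np.isnan(b), a, np.minimum(a, b)))
    return out


def gap_fill_series(values: np.ndarray, period: int, k: int = 4) -> np.ndarray:
    """Seasonal-decomposition gap fill of a composite time series.

    The periodic component (per-position means across periods) is removed,
    gaps in the deseasonalized series are filled by an exponentially weighted
    moving average (weights 2^-|offset| over up to ``k`` composites each
    side, missing neighbors skipped; isolated long gaps fall back to the
    nearest valid value), and the seasonal component is added back. Observed
    values are never altered.

    ``values`` is (n_composites, ...); the series axis is axis 0.
    """
    x = np.asarray(values, dtype=np.result_type(np.asarray(values).dtype, np.float32))
    nt = x.shape[0]
    if nt < 2 * period:
        raise ValueError("series must span at least 2 seasonal periods")
    flat = x.reshape(nt, -1)
    if np.isnan(flat).all(axis=0).any():
        raise ValueError("all-missing series cannot be gap filled")

    pos = np.arange(nt) % period
    seasonal = np.zeros_like(flat)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN positions fall back
        overall = np.nanmean(flat, axis=0)
        for p in range(period):
            rows = pos == p
            m = np.nanmean(flat[rows], axis=0)
            m = np.where(np.isfinite(m), m, overall)
            seasonal[rows] = m
    de = flat - seasonal

    gaps = np.isnan(de)
    num = np.zeros_like(de)
    den = np.zeros_like(de)
    for off in range(1, k + 1):
        w = np.float32(2.0 ** (-off))
        src = de[:-off]
        good = np.isfinite(src)
        num[off:] += w * np.where(good, src, 0)
        den[off:] += w * good
        src = de[off:]
        good = np.isfinite(src)
        num[:-off] += w * np.where(good, src, 0)
        den[:-off] += w * good

    filled = de.copy()
    can = gaps & (den > 0)
    filled[can] = num[can] / den[can]
    # fallback: nearest valid observation in time (rare, long gaps only)
    still = np.isnan(filled)
    if still.any():
        for t, j in zip(*np.nonzero(still)):
            col = de[:, j]
            ok = np.nonzero(np.isfinite(col))[0]
            nearest = ok[np.argmin(np.abs(ok - t))]
            filled[t, j] = col[nearest]
    out = np.where(gaps, filled + seasonal, flat)
    return out.reshape(x.shape)


# ---------------------------------------------------------------------------
# accumulated nocturnal degree-days
# ---------------------------------------------------------------------------


def _days_in_year(year: int) -> int:
    return 366 if dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365


def composite_month_days(start_doy: int, year: int) -> dict[int, int]:
    """Days of an 8-day composite falling in each calendar month."""
    n_days = _days_in_year(year)
    out: dict[int, int] = {}
    for d in range(start_doy, min(start_doy + 8, n_days + 1)):
        month = (dt.date(year, 1, 1) + dt.timedelta(days=d - 1)).month
        out[month] = out.get(month, 0) + 1
    return out


def composite_lengths(start_doys: np.ndarray, year: int) -> np.ndarray:
    """Days covered by each composite (8, truncated at year end)."""
    n_days = _days_in_year(year)
    starts = np.asarray(start_doys)
    if np.any(np.diff(starts) <= 0):
        raise ValueError("composite calendar must be sorted")
    return np.minimum(starts + 8, n_days + 1) - starts


def monthly_andd_contribution(ndd: np.ndarray, start_doys: np.ndarray, year: int, month: int) -> np.ndarray:
    """Degree-days a month accrues: sum over composites of NDD_t x m."""
    total = np.zeros(np.shape(ndd)[1:] if np.ndim(ndd) > 1 else ())
    for t, start in enumerate(start_doys):
        m = composite_month_days(int(start), year).get(month, 0)
        if m:
            total = total + ndd[t] * m
    return total


def compute_andd(
    min_lst_filled: np.ndarray, start_doys: np.ndarray, year: int
) -> dict[tuple[str, int], np.ndarray]:
    """Accumulated nocturnal degree-days, read out semimonthly.

    NDD_t = max(min LST_t - T_base, 0); each composite contributes NDD_t
    times the number of days it covers within the year (split across month
    boundaries), accumulated from 1 January (reset yearly). The semimonthly
    layer for a half-month is the accumulation at the last composite ending
    on or before the half-month's final day.

    Returns {(season, half_index 1-8): raster}.
    """
    lengths = composite_lengths(start_doys, year)
    ndd = np.maximum(np.asarray(min_lst_filled, dtype=float) - T_BASE_C, 0.0)
    if np.isnan(ndd).any():
        raise ValueError("ANDD requires a gap-filled series")
    contrib = ndd * lengths.reshape((-1,) + (1,) * (ndd.ndim - 1))
    cum = np.cumsum(contrib, axis=0)  # accumulation at each composite's end
    end_doys = np.asarray(start_doys) + lengths - 1

    layers: dict[tuple[str, int], np.ndarray] = {}
    for season, months in SEASON_MONTHS.items():
        h = 0
        for month in months:
            last_day = (
                dt.date(year, month + 1, 1) - dt.timedelta(days=1)
                if month < 12
                else dt.date(year, 12, 31)
            ).day
            for end_day in (15, last_day):
                h += 1
                e_doy = dt.date(year, month, end_day).timetuple().tm_yday
                idx = np.searchsorted(end_doys, e_doy, side="right") - 1
                layers[(season, h)] = cum[idx] if idx >= 0 else np.zeros(ndd.shape[1:])
        # monotonicity within the year is inherited from the cumsum
    return layers


def add_andd_layers(stack: PredictorStack, k: int = 4) -> None:
    """Fill LST gaps, compute ANDD, and register the semimonthly layers.

    The seasonal decomposition needs at least two annual cycles, so the
    per-year series are concatenated in calendar order before gap filling.
    """
    years = sorted(stack.lst)
    mins = [min_nightly_lst(stack.lst[y]) for y in years]
    period = len(stack.lst[years[0]].start_doys)
    filled_all = gap_fill_series(np.concatenate(mins, axis=0), period=period, k=k)
    for i, year in enumerate(years):
        series = stack.lst[year]
        filled = filled_all[i * period : (i + 1) * period]
        layers = compute_andd(filled, series.start_doys, year)
        for (season, h), arr in layers.items():
            if season in stack.config.seasons:
                stack.layers[f"andd_{season}_{year}_h{h}"] = arr.astype(np.float32)


# ---------------------------------------------------------------------------
# land-cover aggregation (fine categorical -> 1-km / 5-km predictors)
# ---------------------------------------------------------------------------


def aggregate_landcover(
    lc_fine: np.ndarray,
    canopy_fine: np.ndarray,
    impervious_fine: np.ndarray,
    fine_per_km: int = 40,
    buffer_km: float = 5.0,
) -> dict[str, np.ndarray]:
    """Percent of each merged class per 1-km pixel and 5-km buffer.

    ``lc_fine`` holds national land-cover codes on a fine grid tiling each
    1-km pixel ``fine_per_km`` x ``fine_per_km``; codes 21/22 merge into one
    developed class. Canopy/impervious percent rasters are block-averaged.
    """
    codes = np.unique(lc_fine)
    unknown = [c for c in codes if int(c) not in NLCD_CODE_TO_CLASS]
    if unknown:
        raise ValueError(f"unknown land-cover code(s): {unknown}")
    ny, nx = lc_fine.shape
    if ny % fine_per_km or nx % fine_per_km:
        raise ValueError("fine raster must tile whole 1-km pixels")
    cy, cx = ny // fine_per_km, nx // fine_per_km

    def block_mean(a):
        return a.reshape(cy, fine_per_km, cx, fine_per_km).mean(axis=(1, 3))

    out: dict[str, np.ndarray] = {}
    for cls in LANDCOVER_CLASSES:
        member = np.isin(lc_fine, [k for k, v in NLCD_CODE_TO_CLASS.items() if v == cls])
        out[f"lc1_{cls}"] = 100.0 * block_mean(member.astype(float))
    for cls in LANDCOVER_CLASSES:
        out[f"lc5_{cls}"] = focal_mean(out[f"lc1_{cls}"], buffer_km, 1.0)
    out["canopy"] = block_mean(np.asarray(canopy_fine, dtype=float))
    out["impervious"] = block_mean(np.asarray(impervious_fine, dtype=float))
    return out


# ---------------------------------------------------------------------------
# training-table assembly
# ---------------------------------------------------------------------------


def distance_to_radar_map(grid, stations: list[StationSpec]) -> np.ndarray:
    X, Y = grid.coord_arrays()
    d = np.full(grid.shape, np.inf)
    for s in stations:
        d = np.minimum(d, np.hypot(X - s.x_km, Y - s.y_km))
    return d


def feature_matrix(
    stack: PredictorStack,
    season: str,
    year: int,
    flat_idx: np.ndarray,
    distance_km: np.ndarray,
) -> pd.DataFrame:
    """The 49 predictor columns for a set of pixels (flattened indices)."""
    cols = {}
    for name in predictor_columns():
        if name == "distance_to_radar_km":
            cols[name] = np.asarray(distance_km, dtype=float)
        elif name == "year":
            cols[name] = np.full(len(flat_idx), float(year))
        else:
            layer = stack.layer_for(name, season, year)
            cols[name] = np.asarray(layer, dtype=float).ravel()[flat_idx]
    return pd.DataFrame(cols)


def assemble_training_table(
    stopover_by_year: dict[int, StopoverRaster],
    stack: PredictorStack,
    season: str,
    n_points: int,
    seed: int,
    stations: list[StationSpec],
) -> pd.DataFrame:
    """Sample unique 1-km locations and build (location, year) rows.

    Locations are drawn uniformly without replacement from pixels with
    defined stopover density in every year; each contributes one row per
    year, so no location repeats within a season-year. Rows with any missing
    predictor are dropped (logged).
    """
    grid = stack.grid
    defined = None
    for r in stopover_by_year.values():
        d = np.isfinite(r.values)
        defined = d if defined is None else (defined & d)
    flat_defined = np.nonzero(defined.ravel())[0]
    if n_points > len(flat_defined):
        raise ValueError(
            f"n_points={n_points} exceeds {len(flat_defined)} defined pixels"
        )
    rng = rng_for(seed, "table", season)
    chosen = np.sort(rng.choice(flat_defined, size=n_points, replace=False))

    dist_map = distance_to_radar_map(grid, stations).ravel()[chosen]
    iy, ix = np.divmod(chosen, grid.nx)
    x_km = (ix + 0.5) * grid.pixel_km
    y_km = (iy + 0.5) * grid.pixel_km

    frames = []
    for year, raster in sorted(stopover_by_year.items()):
        feats = feature_matrix(stack, season, year, chosen, dist_map)
        feats.insert(0, "stopover_density", raster.values.ravel()[chosen])
        feats.insert(0, "season", season)
        feats.insert(0, "year_label", year)
        feats.insert(0, "y_km", y_km)
        feats.insert(0, "x_km", x_km)
        feats.insert(0, "loc_id", chosen)
        frames.append(feats)
    table = pd.concat(frames, ignore_index=True)
    n0 = len(table)
    nonmissing = {c: float(table[c].notna().mean()) for c in predictor_columns()}
    table = table.dropna(subset=predictor_columns() + ["stopover_density"]).reset_index(drop=True)
    dropped = n0 - len(table)
    if dropped:
        log.info("dropped %d rows with missing predictors (%.1f%%)", dropped, 100 * dropped / n0)
    table.attrs["n_dropped"] = dropped
    table.attrs["nonmissing_fraction"] = nonmissing
    return table
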