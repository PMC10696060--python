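"""Synthetic landscape generator.

Builds the co-registered 1-km predictor world the niche model consumes:
land-cover composition (15 merged classes at 1-km and 5-km scales), percent
tree canopy and impervious surface, monthly EVI with quality flags, 8-day
nighttime land-surface-temperature series per year, seasonal mean daily
precipitation, skyglow from exponential-decay kernels around random city
points, and elevation. All continuous fields are driven by Gaussian random
fields so the spatial autocorrelation the analysis assumes is present.
"""
from __future__ import annotations

import numpy as np

from ..config import LANDCOVER_CLASSES, SEASON_MONTHS, LandscapeConfig, rng_for
from ..grids import Grid, focal_mean, gaussian_random_field
from ..stack import LSTSeries, PredictorStack, composite_start_doys

# class-prevalence offsets on the logit scale; chosen once to give a
# realistic mix (forest/cultivated common, perennial ice rare)
_CLASS_LOGITS = {
    "water": -1.2,
    "perennial_ice": -4.0,
    "developed": -1.2,
    "developed_medium": -2.6,
    "developed_high": -3.2,
    "barren": -2.5,
    "deciduous": 0.8,
    "evergreen": 0.3,
    "mixed_forest": -0.3,
    "shrub": 0.2,
    "grassland": 0.5,
    "pasture": 0.0,
    "cultivated": 0.8,
    "woody_wetland": -1.0,
    "herbaceous_wetland": -1.8,
}


def _flag_field(grid: Grid, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially blobby boolean mask flagging ~``frac`` of pixels.

    Generated at 4x coarser resolution and block-upsampled; quality-flag
    blobs need no sub-kilometre structure.
    """
    c = 4
    coarse = Grid(nx=max(1, grid.nx // c), ny=max(1, grid.ny // c), pixel_km=grid.pixel_km * c)
    g = gaussian_random_field(coarse, 8.0 * grid.pixel_km, rng)
    thr = np.quantile(g, 1.0 - frac)
    up = np.repeat(np.repeat(g > thr, c, axis=0), c, axis=1)
    if up.shape[0] >= grid.ny and up.shape[1] >= grid.nx:
        return up[: grid.ny, : grid.nx]
    return np.resize(up, grid.shape)


def generate_landscape(config: LandscapeConfig, seed: int) -> PredictorStack:
    """Generate the full predictor stack; deterministic given ``seed``."""
    w, h = config.domain_size_km
    grid = Grid(nx=int(w / config.pixel_km), ny=int(h / config.pixel_km), pixel_km=config.pixel_km)
    stack = PredictorStack(grid=grid, config=config)
    lay = stack.layers
    rng = rng_for(seed, "landscape")

    # --- cities drive both skyglow and the developed classes ---------------
    cities_rng = rng_for(seed, "cities")
    cx = cities_rng.uniform(0, w, config.n_cities)
    cy = cities_rng.uniform(0, h, config.n_cities)
    intensity = np.exp(cities_rng.normal(1.0, 0.8, config.n_cities))
    X, Y = grid.coord_arrays()
    city_field = np.zeros(grid.shape)
    for xi, yi, ii in zip(cx, cy, intensity):
        d = np.hypot(X - xi, Y - yi)
        city_field += ii * np.exp(-d / config.city_kernel_km)

    # --- land cover: softmax of per-class random fields --------------------
    logits = np.empty((len(LANDCOVER_CLASSES),) + grid.shape)
    for i, cls in enumerate(LANDCOVER_CLASSES):
        g = gaussian_random_field(grid, config.grf_range_km, rng_for(seed, "lc", cls))
        logits[i] = 1.5 * g + _CLASS_LOGITS[cls]
        if cls.startswith("developed"):
            logits[i] += 1.5 * np.log1p(city_field)
    logits -= logits.max(axis=0)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0)
    for i, cls in enumerate(LANDCOVER_CLASSES):
        lay[f"lc1_{cls}"] = (100.0 * probs[i]).astype(np.float32)
        lay[f"lc5_{cls}"] = focal_mean(lay[f"lc1_{cls}"], 5.0, grid.pixel_km).astype(np.float32)

    forest = probs[LANDCOVER_CLASSES.index("deciduous")] + probs[
        LANDCOVER_CLASSES.index("evergreen")
    ] + probs[LANDCOVER_CLASSES.index("mixed_forest")]
    developed = sum(
        probs[LANDCOVER_CLASSES.index(c)]
        for c in ("developed", "developed_medium", "developed_high")
    )
    canopy = 60.0 * forest + 10.0 * gaussian_random_field(grid, 20.0, rng_for(seed, "canopy"))
    lay["canopy"] = np.clip(canopy, 0.0, 100.0).astype(np.float32)
    imperv = 85.0 * developed + 3.0 * gaussian_random_field(grid, 15.0, rng_for(seed, "imperv"))
    lay["impervious"] = np.clip(imperv, 0.0, 100.0).astype(np.float32)

    # skyglow is scattered light: diffuse the emission field over a few km
    from scipy import ndimage

    sky = ndimage.gaussian_filter(city_field, sigma=3.0 / config.pixel_km)
    lay["skyglow"] = (0.02 + sky).astype(np.float32)

    elev = 300.0 + 250.0 * gaussian_random_field(grid, config.grf_range_km, rng_for(seed, "elev"))
    lay["elevation"] = np.clip(elev, 0.0, None).astype(np.float32)

    # --- precipitation and EVI per season-year -----------------------------
    for season in config.seasons:
        for year in config.years:
            g = gaussian_random_field(grid, 60.0, rng_for(seed, "precip", season, year))
            lay[f"precip_{season}_{year}"] = (3.0 * np.exp(0.5 * g)).astype(np.float32)
            for m_idx, _month in enumerate(SEASON_MONTHS[season], start=1):
                gm = gaussian_random_field(grid, 30.0, rng_for(seed, "evi", season, year, m_idx))
                evi = 0.15 + 0.5 / (1.0 + np.exp(-(0.02 * (lay["canopy"] - 40.0) + 0.6 * gm)))
                evi = np.clip(evi, 0.0, 1.0).astype(np.float32)
                flags = _flag_field(
                    grid, config.evi_flag_frac, rng_for(seed, "eviflag", season, year, m_idx)
                )
                evi[flags] = np.nan
                lay[f"evi_{season}_{year}_m{m_idx}"] = evi

    # --- nighttime LST series per year -------------------------------------
    t_mean = (
        5.0
        + 2.5 * gaussian_random_field(grid, config.grf_range_km, rng_for(seed, "lstmean"))
        - 0.0065 * (lay["elevation"] - 300.0)
    )
    t_amp = 13.0 + 1.5 * gaussian_random_field(grid, config.grf_range_km, rng_for(seed, "lstamp"))
    doys = composite_start_doys()
    for year in config.years:
        mid = doys + 3.5
        cyc = np.cos(2.0 * np.pi * (mid[:, None, None] - 196.0) / 365.25)
        base = t_mean[None] + t_amp[None] * cyc
        rng_y = rng_for(seed, "lst", year)
        a = base + 0.5 + rng_y.normal(0.0, 1.0, base.shape)
        b = base - 0.7 + rng_y.normal(0.0, 1.0, base.shape)
        a = a.astype(np.float32)
        b = b.astype(np.float32)
        for t in range(len(doys)):
            g = _flag_field(grid, 2 * config.lst_flag_frac, rng_for(seed, "lstflag", year, t))
            rolled = np.roll(g, (grid.ny // 3, grid.nx // 5), axis=(0, 1))
            a[t][g] = np.nan
            b[t][rolled] = np.nan
        stack.lst[year] = LSTSeries(year=year, start_doys=doys, lst_2230=a, lst_0130=b)

    return stack
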