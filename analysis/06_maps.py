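#!/usr/bin/env python
"""Stage 6: hotspot maps, the seasonal difference surface, flyway summaries.

Classifies the predicted surfaces into relative low/medium/high stopover
classes with a 265-km circular focal window (computed on a 4-km aggregation
of the 1-km surface for tractability), forms the fall-minus-spring
difference, and summarises mean predicted density per nominal flyway band.
"""
import json
import pickle
import sys
from pathlib import Path

import numpy as np

from stopover_radar.grids import Grid
from stopover_radar.io import load_raster, save_raster
from stopover_radar.mapping import (
    flyway_summary,
    focal_quantile_classes,
    seasonal_difference,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _coarsen(surface: np.ndarray, f: int) -> np.ndarray:
    ny, nx = surface.shape
    trimmed = surface[: ny // f * f, : nx // f * f]
    blocks = trimmed.reshape(ny // f, f, nx // f, f)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        return np.nanmean(blocks, axis=(1, 3))


def main(seed: int = 1) -> None:
    with open(RESULTS / "cache" / "stage1.pkl", "rb") as f:
        s1 = pickle.load(f)
    cfg = s1["cfg"]
    latest = max(cfg.landscape.years)
    grid = s1["stack"].grid

    surfaces = {}
    for season in cfg.landscape.seasons:
        surface, _ = load_raster(RESULTS / f"predicted_{season}_{latest}.tif")
        surfaces[season] = surface
        coarse = _coarsen(surface, 4)
        hot = focal_quantile_classes(
            coarse, radius_km=cfg.mapping.focal_radius_km, pixel_km=4.0,
            q_mid=cfg.mapping.q_mid, q_hi=cfg.mapping.q_hi,
        )
        save_raster(
            RESULTS / f"hotspots_{season}_{latest}.tif",
            hot.classes.astype(np.float32),
            Grid(nx=coarse.shape[1], ny=coarse.shape[0], pixel_km=4.0),
            meta={"classes": "0=low 1=medium 2=high 255=undefined",
                  "radius_km": cfg.mapping.focal_radius_km},
        )
        f_ = hot.fractions()
        print(f"{season}: hotspot fractions low/medium/high = "
              f"{f_['low']:.2f}/{f_['medium']:.2f}/{f_['high']:.2f}")

    diff, summary = seasonal_difference(surfaces["fall"], surfaces["spring"])
    save_raster(RESULTS / f"seasonal_difference_{latest}.tif", diff, grid)
    print(f"fall higher on {100 * summary['fraction_fall_higher']:.1f}% of pixels; "
          f"mean per-pixel change {summary['mean_pct_change']:.0f}%")

    flyways = {
        season: flyway_summary(surfaces[season], cfg.landscape, grid,
                               cfg.mapping.flyway_boundaries_w)
        for season in surfaces
    }
    out = {"seasonal_difference": summary, "flyways": flyways}
    (RESULTS / "map_summaries.json").write_text(json.dumps(out, indent=1))
    for season, fw in flyways.items():
        ratios = {k: round(v, 2) for k, v in fw["ratios"].items()}
        print(f"{season}: flyway means "
              f"{ {k: round(v, 1) for k, v in fw['means'].items()} }, ratios {ratios}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
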