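"""Hotspot classification, seasonal difference, and flyway summaries.

Hotspots are relative: a pixel is classed against the empirical quantiles of
predicted stopover density within a circular focal window (default radius
265 km, the average nightly flight distance of tracked thrushes) or within a
labeled region. Classes: high >= 90th quantile, medium >= 50th and < 90th,
low < 50th.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LandscapeConfig

CLASS_LOW, CLASS_MEDIUM, CLASS_HIGH, CLASS_UNDEFINED = 0, 1, 2, 255


@dataclass
class HotspotMap:
    classes: np.ndarray  # uint8 raster of CLASS_* values
    meta: dict

    def fractions(self) -> dict[str, float]:
        defined = self.classes != CLASS_UNDEFINED
        n = int(defined.sum())
        if n == 0:
            return {"low": np.nan, "medium": np.nan, "high": np.nan}
        return {
            "low": float((self.classes[defined] == CLASS_LOW).sum()) / n,
            "medium": float((self.classes[defined] == CLASS_MEDIUM).sum()) / n,
            "high": float((self.classes[defined] == CLASS_HIGH).sum()) / n,
        }


def _classify(values: np.ndarray, q50: np.ndarray, q90: np.ndarray) -> np.ndarray:
    out = np.full(values.shape, CLASS_UNDEFINED, dtype=np.uint8)
    defined = np.isfinite(values) & np.isfinite(q50) & np.isfinite(q90)
    out[defined & (values < q50)] = CLASS_LOW
    out[defined & (values >= q50) & (values < q90)] = CLASS_MEDIUM
    out[defined & (values >= q90)] = CLASS_HIGH
    return out


def focal_quantile_classes(
    surface: np.ndarray,
    radius_km: float = 265.0,
    q_mid: float = 0.50,
    q_hi: float = 0.90,
    pixel_km: float = 1.0,
    min_defined: int = 10,
) -> HotspotMap:
    """Relative hotspot classes from quantiles within a circular focal window.

    Quantiles use the inclusive linear-interpolation convention; the window
    is clipped at domain edges; pixels whose window holds fewer than
    ``min_defined`` defined values stay undefined.
    """
    r_px = radius_km / pixel_km
    n = int(np.floor(r_px))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    disc = np.hypot(dx, dy) <= r_px
    dys, dxs = dy[disc], dx[disc]
    ny, nx = surface.shape
    padded = np.full((ny + 2 * n, nx + 2 * n), np.nan)
    padded[n : n + ny, n : n + nx] = surface
    q50 = np.full(surface.shape, np.nan)
    q90 = np.full(surface.shape, np.nan)
    finite = np.isfinite(surface)
    for iy, ix in zip(*np.nonzero(finite)):
        vals = padded[iy + n + dys, ix + n + dxs]
        vals = vals[np.isfinite(vals)]
        if len(vals) >= min_defined:
            q50[iy, ix], q90[iy, ix] = np.quantile(vals, [q_mid, q_hi])
    return HotspotMap(
        classes=_classify(surface, q50, q90),
        meta={"radius_km": radius_km, "q_mid": q_mid, "q_hi": q_hi},
    )


def region_quantile_classes(
    surface: np.ndarray,
    region_labels: np.ndarray,
    q_mid: float = 0.50,
    q_hi: float = 0.90,
    min_defined: int = 10,
) -> HotspotMap:
    """Same class rule with quantiles computed within labeled regions."""
    classes = np.full(surface.shape, CLASS_UNDEFINED, dtype=np.uint8)
    labels = np.asarray(region_labels)
    finite = np.isfinite(surface)
    for lab in np.unique(labels[labels >= 0]):
        sel = (labels == lab) & finite
        if sel.sum() < min_defined:
            continue
        q50, q90 = np.quantile(surface[sel], [q_mid, q_hi])
        sub = np.full(surface.shape, np.nan)
        sub[sel] = surface[sel]
        classes[sel] = _classify(sub, np.full_like(sub, q50), np.full_like(sub, q90))[sel]
    return HotspotMap(classes=classes, meta={"regions": True, "q_mid": q_mid, "q_hi": q_hi})


def seasonal_difference(fall: np.ndarray, spring: np.ndarray) -> tuple[np.ndarray, dict]:
    """Fall minus spring surface and its summary.

    Summary: fraction of defined pixels with a positive difference, and the
    mean per-pixel percent change relative to spring (spring > 0 pixels).
    """
    if fall.shape != spring.shape:
        raise ValueError("surfaces must be co-registered")
    diff = fall - spring
    defined = np.isfinite(diff)
    frac_higher_fall = float((diff[defined] > 0).mean()) if defined.any() else np.nan
    base = defined & np.isfinite(spring) & (spring > 0)
    pct_change = (
        float((100.0 * diff[base] / spring[base]).mean()) if base.any() else np.nan
    )
    return diff, {
        "fraction_fall_higher": frac_higher_fall,
        "mean_pct_change": pct_change,
        "n_defined": int(defined.sum()),
    }


def flyway_labels(config: LandscapeConfig, grid) -> np.ndarray:
    """0=west (>103 degW), 1=central ((90, 103] degW), 2=east (<=90 degW)."""
    lon_w = config.lon_w(grid.x_centers())
    row = np.where(lon_w > 103.0, 0, np.where(lon_w > 90.0, 1, 2))
    return np.tile(row, (grid.ny, 1))


def flyway_summary(
    surface: np.ndarray,
    config: LandscapeConfig,
    grid,
    boundaries_w: tuple[float, float] = (103.0, 90.0),
) -> dict:
    """Per-flyway mean predicted density and pairwise ratios."""
    west_b, east_b = boundaries_w
    lon_w = config.lon_w(grid.x_centers())
    row = np.where(lon_w > west_b, 0, np.where(lon_w > east_b, 1, 2))
    labels = np.tile(row, (grid.ny, 1))
    means = {}
    for lab, name in ((0, "west"), (1, "central"), (2, "east")):
        sel = (labels == lab) & np.isfinite(surface)
        means[name] = float(surface[sel].mean()) if sel.any() else np.nan
    ratios = {}
    for a, b in (("central", "east"), ("central", "west"), ("east", "central"), ("east", "west")):
        if np.isfinite(means[a]) and np.isfinite(means[b]) and means[b] != 0:
            ratios[f"{a}/{b}"] = means[a] / means[b]
    return {"means": means, "ratios": ratios, "boundaries_w": boundaries_w}
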