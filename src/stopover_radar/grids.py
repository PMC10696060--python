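"""Planar 1-km raster grid, Gaussian random fields, and small raster utilities.

The synthetic world lives on a planar equal-area grid in kilometres; arrays
are indexed ``[iy, ix]`` with x increasing along axis 1. Missing cells are
NaN throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Grid:
    """Regular planar grid; pixel (0, 0) is the south-west corner."""

    nx: int
    ny: int
    pixel_km: float = 1.0
    x0_km: float = 0.0
    y0_km: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent_km(self) -> tuple[float, float]:
        return (self.nx * self.pixel_km, self.ny * self.pixel_km)

    def x_centers(self) -> np.ndarray:
        return self.x0_km + (np.arange(self.nx) + 0.5) * self.pixel_km

    def y_centers(self) -> np.ndarray:
        return self.y0_km + (np.arange(self.ny) + 0.5) * self.pixel_km

    def coord_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinate arrays of shape (ny, nx)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def pixel_index(self, x_km, y_km) -> tuple[np.ndarray, np.ndarray]:
        """(iy, ix) of the pixel containing each point; no bounds check."""
        ix = np.floor((np.asarray(x_km) - self.x0_km) / self.pixel_km).astype(np.int64)
        iy = np.floor((np.asarray(y_km) - self.y0_km) / self.pixel_km).astype(np.int64)
        return iy, ix

    def contains(self, x_km, y_km) -> np.ndarray:
        w, h = self.extent_km
        x = np.asarray(x_km) - self.x0_km
        y = np.asarray(y_km) - self.y0_km
        return (x >= 0) & (x < w) & (y >= 0) & (y < h)


def gaussian_random_field(grid: Grid, range_km: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian random field with unit variance and zero mean.

    White noise smoothed by a Gaussian kernel whose sd equals ``range_km``
    (periodic boundary, so the field is stationary across the domain), then
    standardised empirically.
    """
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    white = rng.standard_normal(grid.shape)
    sigma_px = range_km / grid.pixel_km
    field = ndimage.gaussian_filter(white, sigma=sigma_px, mode="wrap")
    field -= field.mean()
    sd = field.std()
    if sd == 0:
        return field
    return (field / sd).astype(np.float64)


def disc_kernel(radius_km: float, pixel_km: float) -> np.ndarray:
    """Binary circular kernel; membership by pixel-center distance <= radius."""
    r_px = radius_km / pixel_km
    n = int(np.floor(r_px))
    offs = np.arange(-n, n + 1)
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    return (np.hypot(xx, yy) <= r_px).astype(float)


def focal_mean(field: np.ndarray, radius_km: float, pixel_km: float) -> np.ndarray:
    """Mean of ``field`` within a circular buffer around every pixel.

    NaN-aware: missing cells are excluded from both numerator and count.
    """
    kernel = disc_kernel(radius_km, pixel_km)
    valid = np.isfinite(field).astype(float)
    filled = np.where(np.isfinite(field), field, 0.0)
    # constant-zero padding clips the buffer at domain edges
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    out = np.full(field.shape, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def zscore(layer: np.ndarray) -> np.ndarray:
    """Standardise a raster layer, ignoring NaN; constant layers map to 0."""
    mu = np.nanmean(layer)
    sd = np.nanstd(layer)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(layer, dtype=float)
    return (layer - mu) / sd
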