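"""Co-registered predictor rasters and their naming scheme.

Concrete layer names are ``lc1_<class>``, ``lc5_<class>``, ``canopy``,
``impervious``, ``skyglow``, ``elevation`` (static) and
``evi_<season>_<year>_m<1-4>``, ``andd_<season>_<year>_h<1-8>``,
``precip_<season>_<year>`` (season/year specific). The 49 model predictor
columns map onto these via :meth:`PredictorStack.layer_for`.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .config import LandscapeConfig
from .grids import Grid


@dataclass
class LSTSeries:
    """8-day nighttime land-surface-temperature composites (degC).

    Two platform series per the two nominal nighttime overpasses; NaN marks
    quality-filtered composites. ``start_doys`` are composite start
    days-of-year (1, 9, ..., 361).
    """

    year: int
    start_doys: np.ndarray
    lst_2230: np.ndarray  # (n_composites, ny, nx)
    lst_0130: np.ndarray

    def __post_init__(self):
        if self.lst_2230.shape != self.lst_0130.shape:
            raise ValueError("platform series must be aligned")
        if len(self.start_doys) != self.lst_2230.shape[0]:
            raise ValueError("calendar length must match series length")


def composite_start_doys(n: int = 46) -> np.ndarray:
    return np.arange(n) * 8 + 1


_SEASONAL = re.compile(r"^(evi_m[1-4]|andd_h[1-8]|precip)$")


@dataclass
class PredictorStack:
    grid: Grid
    config: LandscapeConfig
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    lst: dict[int, LSTSeries] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def layer_for(self, column: str, season: str, year: int) -> np.ndarray:
        """Resolve a predictor column name to its concrete raster."""
        if column == "precip":
            key = f"precip_{season}_{year}"
        elif _SEASONAL.match(column):
            base, suffix = column.split("_")
            key = f"{base}_{season}_{year}_{suffix}"
        else:
            key = column
        if key not in self.layers:
            raise KeyError(f"unknown predictor layer {column!r} (resolved {key!r})")
        return self.layers[key]

    def landcover_fraction_names(self, scale: str) -> list[str]:
        prefix = {"1km": "lc1_", "5km": "lc5_"}[scale]
        return [k for k in self.layers if k.startswith(prefix)]
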