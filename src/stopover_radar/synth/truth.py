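"""Known ground-truth stopover-density surface.

Density is lognormal in the predictors: log density = intercept + beta-weighted
standardised predictors + a spatially correlated residual field + iid pixel
noise, optionally scaled by a seasonal factor. Because the truth model is
known, every downstream stage (radar measurement, niche model, directionality
classification) can be checked against planted parameters.
"""
from __future__ import annotations

import numpy as np

from ..config import TruthModel, rng_for
from ..grids import gaussian_random_field, zscore
from ..stack import PredictorStack


def _soft_clip(z: np.ndarray, at: float = 3.0) -> np.ndarray:
    """Strictly monotone tail compression: identity within ``at`` sd.

    Heavily skewed layers (skyglow near city cores) otherwise contribute
    tens of sd to the log-density and produce physically absurd densities;
    beyond ``at`` the excess is compressed logarithmically.
    """
    a = np.abs(z)
    excess = np.log1p(np.maximum(a - at, 0.0))
    return np.where(a <= at, z, np.sign(z) * (at + excess))


def truth_signal(stack: PredictorStack, truth: TruthModel, season: str, year: int) -> np.ndarray:
    """The beta-weighted standardised linear predictor (before noise)."""
    signal = np.zeros(stack.grid.shape)
    for name, beta in truth.coefficients.items():
        try:
            layer = stack.layer_for(name, season, year)
        except KeyError as exc:
            raise KeyError(f"truth coefficient names unknown predictor {name!r}") from exc
        z = _soft_clip(zscore(np.asarray(layer, dtype=float)))
        signal += beta * np.where(np.isfinite(z), z, 0.0)
    if truth.signal_sd is not None:
        sd = signal.std()
        if sd > 0:
            signal *= truth.signal_sd / sd
    return signal


def generate_truth_density(
    stack: PredictorStack, truth: TruthModel, season: str, year: int, seed: int
) -> np.ndarray:
    """Strictly positive density raster (cm^2/km^2); deterministic given seed.

    The spatial residual field is static across years (unmodelled habitat
    quality); the iid observation noise is drawn per season-year.
    """
    log_density = truth.intercept + truth_signal(stack, truth, season, year)
    if truth.spatial_noise_sd > 0:
        g = gaussian_random_field(stack.grid, truth.noise_range_km, rng_for(seed, "truthgrf"))
        log_density = log_density + truth.spatial_noise_sd * g
    if truth.obs_noise_sd > 0:
        rng = rng_for(seed, "truthobs", season, year)
        log_density = log_density + truth.obs_noise_sd * rng.standard_normal(stack.grid.shape)
    scale = truth.season_scale.get(season, 1.0)
    return scale * np.exp(log_density)
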