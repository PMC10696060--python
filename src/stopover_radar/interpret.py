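"""Variable importance, partial dependence, and directionality.

Importance is gain (fractional loss reduction attributable to splits on a
feature), normalized within each model and averaged across the box ensemble.
Directionality follows a slope-vote rule: per model, an OLS line is fit to
the partial-dependence predictions; among models with a significant slope
(p < 0.05), a variable is globally positive if more than 55% of slopes are
positive and negative if fewer than 45% are.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import rng_for
from .model import ModelBox
from .predictors import predictor_columns, predictor_registry
from .stack import PredictorStack


@dataclass
class PDPCurve:
    variable: str
    grid: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        if len(self.grid) < 2 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("PDP grid must be strictly increasing")


@dataclass
class DirectionalityRecord:
    variable: str
    mean_gain: float
    n_models: int
    n_significant: int
    pct_positive: float | None
    classification: str  # positive | negative | neutral | insufficient


def mean_gain(boxes: list[ModelBox]) -> pd.Series:
    """Per-variable gain, normalized to sum to 1 per model, then averaged."""
    if not boxes:
        raise ValueError("no fitted boxes")
    features = predictor_columns()
    rows = []
    for box in boxes:
        g = np.array([box.gain.get(f, 0.0) for f in features], dtype=float)
        total = g.sum()
        rows.append(g / total if total > 0 else g)
    return pd.Series(np.mean(rows, axis=0), index=features)


def partial_dependence(box: ModelBox, variable: str, grid_size: int = 50) -> PDPCurve:
    """Model response along one variable, all others at training medians.

    The grid spans the variable's observed range in the box's training rows.
    """
    features = predictor_columns()
    if variable not in features:
        raise KeyError(variable)
    lo = float(box.feature_ranges.loc["min", variable])
    hi = float(box.feature_ranges.loc["max", variable])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError(f"degenerate range for {variable!r}")
    grid = np.linspace(lo, hi, grid_size)
    X = pd.DataFrame(
        np.tile(box.medians[features].to_numpy(), (grid_size, 1)), columns=features
    )
    X[variable] = grid
    pred = box.model.predict(X)
    return PDPCurve(variable=variable, grid=grid, predicted=np.asarray(pred, dtype=float))


def pdp_slope(curve: PDPCurve) -> tuple[float, float]:
    """OLS slope of the PDP predictions on the grid, with its p-value."""
    if np.allclose(curve.predicted, curve.predicted[0]):
        return 0.0, 1.0
    fit = stats.linregress(curve.grid, curve.predicted)
    return float(fit.slope), float(fit.pvalue)


def classify_directionality(
    curves: list[PDPCurve],
    mean_gain_value: float = float("nan"),
    alpha: float = 0.05,
    pos_hi: float = 0.55,
    pos_lo: float = 0.45,
    among_significant: bool = True,
) -> DirectionalityRecord:
    """Slope-vote classification of one variable across the box ensemble."""
    if not curves:
        raise ValueError("no PDP curves")
    variable = curves[0].variable
    slopes = []
    for c in curves:
        s, p = pdp_slope(c)
        slopes.append((s, p))
    sig = [s for s, p in slopes if p < alpha]
    denom = sig if among_significant else [s for s, _ in slopes]
    if not sig:
        return DirectionalityRecord(variable, mean_gain_value, len(curves), 0, None, "insufficient")
    pct_pos = 100.0 * sum(1 for s in denom if s > 0) / len(denom)
    if pct_pos > 100.0 * pos_hi:
        cls = "positive"
    elif pct_pos < 100.0 * pos_lo:
        cls = "negative"
    else:
        cls = "neutral"
    return DirectionalityRecord(variable, mean_gain_value, len(curves), len(sig), pct_pos, cls)


def directionality_table(
    boxes: list[ModelBox],
    variables: list[str] | None = None,
    grid_size: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean gain + directionality class for each variable across boxes."""
    variables = variables or predictor_columns()
    gains = mean_gain(boxes)
    records = []
    for var in variables:
        curves = []
        for box in boxes:
            try:
                curves.append(partial_dependence(box, var, grid_size))
            except ValueError:
                continue
        if not curves:
            continue
        rec = classify_directionality(curves, mean_gain_value=float(gains[var]), alpha=alpha)
        records.append(rec.__dict__)
    return pd.DataFrame(records)


def category_gain_summary(gain: pd.Series, registry: dict[str, str] | None = None) -> pd.Series:
    """Percent of summed gain per predictor category (sampling terms removed).

    Distance to radar and year are excluded before pooling; the rest sum to
    100 percent.
    """
    registry = registry or predictor_registry()
    missing = [v for v in gain.index if v not in registry]
    if missing:
        raise KeyError(f"uncategorized variable(s): {missing}")
    keep = gain[[v for v in gain.index if registry[v] not in ("distance_to_radar", "year")]]
    pooled = keep.groupby([registry[v] for v in keep.index]).sum()
    total = pooled.sum()
    if total <= 0:
        raise ValueError("no gain to pool")
    return 100.0 * pooled / total


def predictor_correlation_experiment(
    stack: PredictorStack,
    pairs: list[tuple[str, str]],
    n_draws: int = 10_000,
    n_locs: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Pearson correlations from repeated small random draws.

    Per draw, ``n_locs`` pixels are sampled and r with its two-sided p-value
    computed per pair; the summary is the median r and the fraction of
    significant draws.
    """
    rng = rng_for(seed, "corr")
    results = []
    for name_a, name_b in pairs:
        a = np.asarray(stack.layers[name_a], dtype=float).ravel()
        b = np.asarray(stack.layers[name_b], dtype=float).ravel()
        valid = np.nonzero(np.isfinite(a) & np.isfinite(b))[0]
        if len(valid) < n_locs:
            raise ValueError(f"fewer than {n_locs} valid pixels for {name_a} vs {name_b}")
        idx = rng.choice(valid, size=(n_draws, n_locs), replace=True)
        xa = a[idx]
        xb = b[idx]
        xa = xa - xa.mean(axis=1, keepdims=True)
        xb = xb - xb.mean(axis=1, keepdims=True)
        denom = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xa * xb).sum(axis=1) / denom
        r = np.clip(r, -1.0, 1.0)
        dfree = n_locs - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(dfree / np.maximum(1e-300, 1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), dfree)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        results.append(
            {
                "pair": f"{name_a}~{name_b}",
                "median_r": float(np.median(r)),
                "pct_significant": 100.0 * float(np.mean(p < alpha)),
            }
        )
    return pd.DataFrame(results)
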