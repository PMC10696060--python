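"""Spatially partitioned gradient-boosted niche model.

The domain is tiled with randomly centered square bounding boxes; each box
trains its own boosted regression-tree model on the rows inside it, which
prevents associations learned in one region from driving predictions in a
distant one ("long-distance learning"). Predictions are mosaicked by
averaging overlapping boxes; model transfer is assessed by holding out a
10-km block centered on the median of each box's training locations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .config import BoostConfig, HoldoutConfig, rng_for
from .predictors import feature_matrix, predictor_columns
from .stack import PredictorStack

log = logging.getLogger(__name__)

SPLIT_TRAIN, SPLIT_VAL, SPLIT_TEST = 0, 1, 2


@dataclass
class BoxSpec:
    center_x_km: float
    center_y_km: float
    side_km: float
    # bounds clipped to the domain
    x0: float
    x1: float
    y0: float
    y1: float

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass
class ModelBox:
    spec: BoxSpec
    model: xgb.XGBRegressor
    gain: dict[str, float]
    medians: pd.Series
    feature_ranges: pd.DataFrame
    n_train: int
    test_r2: float | None = None
    meta: dict = field(default_factory=dict)


def spatial_partition(
    domain_size_km: tuple[float, float],
    n_small: int,
    n_large: int,
    side_small_km: float,
    side_large_km: float,
    seed: int,
) -> list[BoxSpec]:
    """Square boxes centered on uniform random points, clipped to the domain."""
    if n_small + n_large <= 0:
        raise ValueError("need at least one box")
    w, h = domain_size_km
    rng = rng_for(seed, "partition")
    boxes = []
    for n, side in ((n_small, side_small_km), (n_large, side_large_km)):
        for _ in range(n):
            cx = float(rng.uniform(0, w))
            cy = float(rng.uniform(0, h))
            boxes.append(
                BoxSpec(
                    center_x_km=cx,
                    center_y_km=cy,
                    side_km=side,
                    x0=max(0.0, cx - side / 2),
                    x1=min(w, cx + side / 2),
                    y0=max(0.0, cy - side / 2),
                    y1=min(h, cy + side / 2),
                )
            )
    return boxes


def _mix64(v: np.ndarray) -> np.ndarray:
    v = v.copy()
    v ^= v >> np.uint64(33)
    v *= np.uint64(0xFF51AFD7ED558CCD)
    v ^= v >> np.uint64(33)
    v *= np.uint64(0xC4CEB9FE1A85EC53)
    v ^= v >> np.uint64(33)
    return v


def location_split(
    loc_id: np.ndarray, seed: int, fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
) -> np.ndarray:
    """Location-level train/validation/test assignment by hashing pixel ids.

    Order-independent and reproducible: every row of a location shares one
    assignment, and the assignment does not depend on which rows are present.
    """
    with np.errstate(over="ignore"):  # modular 64-bit arithmetic is intended
        h = _mix64(
            np.asarray(loc_id, dtype=np.uint64) * np.uint64(0x9E3779B97F4A7C15)
            + np.uint64((seed & 0xFFFFFFFF) * 0xC2B2AE3D27D4EB4F & 0xFFFFFFFFFFFFFFFF)
        )
    u = h.astype(np.float64) / float(2**64)
    out = np.full(len(u), SPLIT_TEST, dtype=np.int8)
    out[u < fractions[0] + fractions[1]] = SPLIT_VAL
    out[u < fractions[0]] = SPLIT_TRAIN
    return out


def _fit_xgb(
    X_train, y_train, X_val, y_val, cfg: BoostConfig, learning_rate=None,
    colsample=None, subsample=None, n_estimators=None,
) -> xgb.XGBRegressor:
    model = xgb.XGBRegressor(
        max_depth=cfg.max_depth,
        min_child_weight=cfg.min_child_weight,
        gamma=cfg.gamma,
        colsample_bytree=cfg.colsample_bytree if colsample is None else colsample,
        subsample=cfg.subsample if subsample is None else subsample,
        learning_rate=cfg.learning_rate if learning_rate is None else learning_rate,
        n_estimators=cfg.n_estimators if n_estimators is None else n_estimators,
        early_stopping_rounds=cfg.early_stopping_rounds,
        objective="reg:squarederror",
        tree_method="hist",
        max_bin=cfg.max_bin,
        n_jobs=1,
        random_state=cfg.seed,
        verbosity=0,
    )
    model.fit(X_train, y_train, eval_set=[(X_val, y_val)], verbose=False)
    return model


def _gain_dict(model: xgb.XGBRegressor, features: list[str]) -> dict[str, float]:
    raw = model.get_booster().get_score(importance_type="gain")
    # booster keys are feature names when a DataFrame was used
    return {f: float(raw.get(f, 0.0)) for f in features}


def train_box_model(
    rows: pd.DataFrame,
    spec: BoxSpec,
    cfg: BoostConfig,
    min_rows: int = 50,
) -> ModelBox | None:
    """Fit one box's boosted-tree model; boosting rounds by early stopping.

    Rows must carry a ``split`` column (location-level assignment). Boxes
    with fewer than ``min_rows`` rows are skipped with a logged reason.
    """
    if len(rows) < min_rows:
        log.info("box at (%.0f, %.0f) skipped: %d rows < %d",
                 spec.center_x_km, spec.center_y_km, len(rows), min_rows)
        return None
    features = predictor_columns()
    train = rows[rows["split"] == SPLIT_TRAIN]
    val = rows[rows["split"] == SPLIT_VAL]
    test = rows[rows["split"] == SPLIT_TEST]
    if len(train) < 10 or len(val) < 5:
        log.info("box at (%.0f, %.0f) skipped: degenerate split", spec.center_x_km, spec.center_y_km)
        return None
    model = _fit_xgb(
        train[features], train["stopover_density"], val[features], val["stopover_density"], cfg
    )
    test_r2 = None
    if len(test) >= 3:
        pred = model.predict(test[features])
        ss_res = float(((test["stopover_density"] - pred) ** 2).sum())
        ss_tot = float(((test["stopover_density"] - test["stopover_density"].mean()) ** 2).sum())
        test_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return ModelBox(
        spec=spec,
        model=model,
        gain=_gain_dict(model, features),
        medians=train[features].median(),
        feature_ranges=train[features].agg(["min", "max"]),
        n_train=len(train),
        test_r2=test_r2,
    )


def train_partition(
    table: pd.DataFrame, boxes: list[BoxSpec], cfg: BoostConfig, min_rows: int = 50
) -> list[ModelBox]:
    fitted = []
    for spec in boxes:
        rows = table[spec.contains(table["x_km"], table["y_km"])]
        box = train_box_model(rows, spec, cfg, min_rows=min_rows)
        if box is not None:
            fitted.append(box)
    return fitted


def predict_surface(
    boxes: list[ModelBox],
    stack: PredictorStack,
    season: str,
    year: int,
    stations,
    fixed_distance_km: float = 35.0,
) -> np.ndarray:
    """Mosaicked 1-km prediction with distance-to-radar fixed at 35 km.

    Each box predicts every pixel inside its bounds from the given year's
    predictor layers; overlapping predictions are averaged; uncovered pixels
    stay missing.
    """
    if not boxes:
        raise ValueError("no fitted boxes")
    grid = stack.grid
    X, Y = grid.coord_arrays()
    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape)
    features = predictor_columns()
    for box in boxes:
        inside = box.spec.contains(X, Y)
        flat = np.nonzero(inside.ravel())[0]
        if flat.size == 0:
            continue
        feats = feature_matrix(
            stack, season, year, flat, np.full(flat.size, float(fixed_distance_km))
        )
        ok = feats[features].notna().all(axis=1).to_numpy()
        pred = np.full(flat.size, np.nan)
        if ok.any():
            pred[ok] = box.model.predict(feats.loc[ok, features])
        iy, ix = np.divmod(flat, grid.nx)
        good = np.isfinite(pred)
        sums[iy[good], ix[good]] += pred[good]
        counts[iy[good], ix[good]] += 1.0
    out = np.full(grid.shape, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


# ---------------------------------------------------------------------------
# spatial holdout experiment
# ---------------------------------------------------------------------------


def run_holdout(
    spec: BoxSpec,
    rows: pd.DataFrame,
    hcfg: HoldoutConfig,
    cfg: BoostConfig,
) -> pd.DataFrame:
    """Hold out a 10-km block at the median location of a box's rows.

    If fewer than ``min_points`` rows fall in the block the box is excluded
    (empty frame). Otherwise the model is retrained on the remaining rows
    with the holdout hyperparameters and predictions are emitted for the
    held rows.
    """
    if len(rows) == 0:
        return pd.DataFrame()
    mx = float(rows["x_km"].median())
    my = float(rows["y_km"].median())
    half = hcfg.holdout_side_km / 2.0
    held_mask = (
        (rows["x_km"] >= mx - half)
        & (rows["x_km"] <= mx + half)
        & (rows["y_km"] >= my - half)
        & (rows["y_km"] <= my + half)
    )
    held = rows[held_mask]
    if len(held) < hcfg.min_points:
        return pd.DataFrame()
    rest = rows[~held_mask]
    features = predictor_columns()
    train = rest[rest["split"] == SPLIT_TRAIN]
    val = rest[rest["split"] == SPLIT_VAL]
    if len(train) < 10 or len(val) < 5:
        return pd.DataFrame()
    assert not set(held.index) & set(train.index)
    model = _fit_xgb(
        train[features],
        train["stopover_density"],
        val[features],
        val["stopover_density"],
        cfg,
        learning_rate=hcfg.learning_rate,
        colsample=hcfg.colsample_bytree,
        subsample=hcfg.subsample,
        n_estimators=hcfg.n_estimators,
    )
    pred = model.predict(held[features])
    return pd.DataFrame(
        {
            "loc_id": held["loc_id"].to_numpy(),
            "year": held["year_label"].to_numpy(),
            "predicted": pred,
            "actual": held["stopover_density"].to_numpy(),
        }
    )


def evaluate_holdout(predictions: pd.DataFrame, seed: int) -> dict:
    """Pooled holdout fit: R^2, slope, intercept and n.

    Duplicate (location, year) predictions are averaged; one year is kept
    per location uniformly at random; then predicted is regressed on actual
    by ordinary least squares.
    """
    if len(predictions) == 0:
        raise ValueError("empty holdout pool")
    pooled = (
        predictions.groupby(["loc_id", "year"], as_index=False)[["predicted", "actual"]].mean()
    )
    rng = rng_for(seed, "holdout-year")
    picked = []
    for _, grp in pooled.groupby("loc_id"):
        picked.append(grp.iloc[int(rng.integers(len(grp)))])
    final = pd.DataFrame(picked)
    if len(final) < 3:
        raise ValueError("fewer than 3 pooled holdout points")
    fit = stats.linregress(final["actual"], final["predicted"])
    return {
        "r2": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(final)),
    }


def holdout_experiment(
    table: pd.DataFrame,
    boxes: list[BoxSpec],
    hcfg: HoldoutConfig,
    cfg: BoostConfig,
    sides_km: float | None = None,
) -> pd.DataFrame:
    """Run the holdout over the given boxes (optionally one side class)."""
    frames = []
    n_excluded = 0
    for spec in boxes:
        if sides_km is not None and spec.side_km != sides_km:
            continue
        rows = table[spec.contains(table["x_km"], table["y_km"])]
        out = run_holdout(spec, rows, hcfg, cfg)
        if len(out) == 0:
            n_excluded += 1
        else:
            frames.append(out)
    log.info("holdout: %d boxes contributed, %d excluded", len(frames), n_excluded)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
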