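"""Partitioned boosted-tree training, prediction mosaicking, and holdout."""
import numpy as np
import pandas as pd
import pytest

from stopover_radar.config import BoostConfig, HoldoutConfig
from stopover_radar.model import (
    SPLIT_TEST,
    SPLIT_TRAIN,
    SPLIT_VAL,
    BoxSpec,
    evaluate_holdout,
    location_split,
    run_holdout,
    spatial_partition,
    train_box_model,
)
from stopover_radar.predictors import predictor_columns


def _synthetic_rows(n, seed, response="linear", noise=0.0):
    rng = np.random.default_rng(seed)
    cols = predictor_columns()
    df = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
    df.insert(0, "loc_id", np.arange(n))
    df.insert(1, "x_km", rng.uniform(0, 100, n))
    df.insert(2, "y_km", rng.uniform(0, 100, n))
    df.insert(3, "year_label", rng.choice([2019, 2020], n))
    if response == "linear":
        y = 3.0 * df["skyglow"].to_numpy()
    else:
        y = rng.normal(size=n)
    df["stopover_density"] = y + noise * rng.normal(size=n)
    df["split"] = location_split(df["loc_id"].to_numpy(), seed)
    return df


# ---------------------------------------------------------------------------
# partitioning and splitting
# ---------------------------------------------------------------------------


def test_partition_counts_continental_scale():
    boxes = spatial_partition((4000, 2600), 2000, 500, 400.0, 800.0, seed=1)
    assert sum(1 for b in boxes if b.side_km == 400.0) == 2000
    assert sum(1 for b in boxes if b.side_km == 800.0) == 500


def test_partition_clips_to_domain_and_is_deterministic():
    a = spatial_partition((100, 100), 30, 0, 80.0, 160.0, seed=5)
    b = spatial_partition((100, 100), 30, 0, 80.0, 160.0, seed=5)
    assert [(s.x0, s.x1, s.y0, s.y1) for s in a] == [(s.x0, s.x1, s.y0, s.y1) for s in b]
    for s in a:
        assert 0 <= s.x0 <= s.x1 <= 100
        assert 0 <= s.y0 <= s.y1 <= 100


def test_partition_membership_matches_bruteforce():
    boxes = spatial_partition((512, 512), 20, 0, 200.0, 400.0, seed=2)
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 512, 1000)
    y = rng.uniform(0, 512, 1000)
    for spec in boxes:
        got = spec.contains(x, y)
        expected = (x >= spec.x0) & (x <= spec.x1) & (y >= spec.y0) & (y <= spec.y1)
        np.testing.assert_array_equal(got, expected)


def test_partition_requires_boxes():
    with pytest.raises(ValueError):
        spatial_partition((100, 100), 0, 0, 10.0, 20.0, seed=1)


def test_location_split_is_location_level_and_orderfree():
    ids = np.arange(100_000)
    s1 = location_split(ids, seed=9)
    perm = np.random.default_rng(0).permutation(len(ids))
    s2 = location_split(ids[perm], seed=9)
    np.testing.assert_array_equal(s1[perm], s2)
    fracs = [np.mean(s1 == k) for k in (SPLIT_TRAIN, SPLIT_VAL, SPLIT_TEST)]
    assert fracs[0] == pytest.approx(0.75, abs=0.01)
    assert fracs[1] == pytest.approx(0.15, abs=0.01)
    assert fracs[2] == pytest.approx(0.10, abs=0.01)
    # pairwise disjoint by construction: one label per location
    assert set(np.unique(s1)) <= {SPLIT_TRAIN, SPLIT_VAL, SPLIT_TEST}


def test_location_split_differs_across_seeds():
    ids = np.arange(1000)
    assert (location_split(ids, 1) != location_split(ids, 2)).any()


# ---------------------------------------------------------------------------
# box training
# ---------------------------------------------------------------------------


def _domain_box():
    return BoxSpec(50.0, 50.0, 100.0, 0.0, 100.0, 0.0, 100.0)


def test_box_model_learns_exact_linear_target():
    rows = _synthetic_rows(3000, seed=1, response="linear")
    box = train_box_model(rows, _domain_box(), BoostConfig(seed=1))
    assert box is not None
    assert box.test_r2 >= 0.99


def test_box_model_no_signal_r2_near_zero():
    rows = _synthetic_rows(3000, seed=2, response="noise")
    box = train_box_model(rows, _domain_box(), BoostConfig(seed=2, n_estimators=60))
    assert box is not None
    assert box.test_r2 < 0.1


def test_box_model_deterministic_gain():
    rows = _synthetic_rows(1500, seed=3, response="linear", noise=0.3)
    cfg = BoostConfig(seed=3, n_estimators=40)
    a = train_box_model(rows, _domain_box(), cfg)
    b = train_box_model(rows, _domain_box(), cfg)
    assert a.gain == b.gain


def test_box_model_skips_small_boxes(caplog):
    rows = _synthetic_rows(20, seed=4)
    assert train_box_model(rows, _domain_box(), BoostConfig(seed=4), min_rows=50) is None


def test_spatial_partitioning_prevents_long_distance_learning():
    """A west-only association must not drive eastern-box responses.

    The response follows +3*skyglow in the west half of the domain and
    -3*skyglow in the east half; boxes confined to each half must recover
    their own region's slope sign.
    """
    from stopover_radar.interpret import partial_dependence, pdp_slope

    rng = np.random.default_rng(11)
    n = 6000
    cols = predictor_columns()
    df = pd.DataFrame(rng.uniform(-2, 2, size=(n, len(cols))), columns=cols)
    df["loc_id"] = np.arange(n)
    df["x_km"] = rng.uniform(0, 400, n)
    df["y_km"] = rng.uniform(0, 200, n)
    df["year_label"] = 2019
    west = df["x_km"] < 200
    df["stopover_density"] = np.where(west, 3.0, -3.0) * df["skyglow"]
    df["split"] = location_split(df["loc_id"].to_numpy(), 11)
    cfg = BoostConfig(seed=11, n_estimators=80)
    west_box = BoxSpec(100.0, 100.0, 200.0, 0.0, 200.0, 0.0, 200.0)
    east_box = BoxSpec(300.0, 100.0, 200.0, 200.0, 400.0, 0.0, 200.0)
    slopes = {}
    for name, spec in (("west", west_box), ("east", east_box)):
        rows = df[spec.contains(df["x_km"], df["y_km"])]
        box = train_box_model(rows, spec, cfg)
        slopes[name] = pdp_slope(partial_dependence(box, "skyglow"))[0]
    assert slopes["west"] == pytest.approx(3.0, rel=0.2)
    assert slopes["east"] == pytest.approx(-3.0, rel=0.2)


# ---------------------------------------------------------------------------
# prediction surface
# ---------------------------------------------------------------------------


def test_predict_surface_single_box_verbatim_and_mean_of_duplicates(tiny_stack, tiny_model):
    from stopover_radar.config import StationSpec
    from stopover_radar.model import predict_surface

    stations = [StationSpec("T01", 48.0, 48.0)]
    one = predict_surface([tiny_model], tiny_stack, "spring", 2020, stations)
    two = predict_surface([tiny_model, tiny_model], tiny_stack, "spring", 2020, stations)
    # duplicated boxes average to the single-box surface
    np.testing.assert_allclose(one, two, equal_nan=True)
    assert np.isfinite(one).any()


def test_predict_surface_mean_of_two_boxes(tiny_stack, tiny_model):
    from stopover_radar.model import ModelBox, predict_surface

    class _Const:
        def __init__(self, v):
            self.v = v

        def predict(self, X):
            return np.full(len(X), self.v)

    def fake(v):
        return ModelBox(
            spec=tiny_model.spec, model=_Const(v), gain={}, medians=tiny_model.medians,
            feature_ranges=tiny_model.feature_ranges, n_train=1,
        )

    out = predict_surface([fake(2.0), fake(10.0)], tiny_stack, "spring", 2020, [])
    assert np.nanmax(np.abs(out - 6.0)) < 1e-12


def test_predict_surface_requires_boxes(tiny_stack):
    from stopover_radar.model import predict_surface

    with pytest.raises(ValueError):
        predict_surface([], tiny_stack, "spring", 2020, [])


# ---------------------------------------------------------------------------
# holdout
# ---------------------------------------------------------------------------


def test_holdout_excludes_boxes_under_25_points():
    rows = _synthetic_rows(200, seed=5)
    # scatter rows widely: < 25 inside any 10-km block
    out = run_holdout(_domain_box(), rows, HoldoutConfig(), BoostConfig(seed=5))
    assert len(out) == 0


def test_holdout_centers_on_median_and_keeps_held_rows_out():
    rows = _synthetic_rows(3000, seed=6, response="linear", noise=0.1)
    # concentrate locations so the 10-km box is populated
    rng = np.random.default_rng(1)
    rows["x_km"] = rng.uniform(45, 55, len(rows))
    rows["y_km"] = rng.uniform(45, 55, len(rows))
    out = run_holdout(_domain_box(), rows, HoldoutConfig(), BoostConfig(seed=6, n_estimators=40))
    assert len(out) >= 25
    mx, my = rows["x_km"].median(), rows["y_km"].median()
    held = rows[
        rows["x_km"].between(mx - 5, mx + 5) & rows["y_km"].between(my - 5, my + 5)
    ]
    assert len(out) == len(held)
    assert set(zip(out["loc_id"], out["year"])) == set(
        zip(held["loc_id"], held["year_label"])
    )


def test_evaluate_holdout_perfect_predictions():
    preds = pd.DataFrame(
        {
            "loc_id": np.arange(50),
            "year": 2019,
            "actual": np.linspace(1, 9, 50),
            "predicted": np.linspace(1, 9, 50),
        }
    )
    fit = evaluate_holdout(preds, seed=1)
    assert fit["r2"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(1.0)
    assert fit["n"] == 50


def test_evaluate_holdout_averages_duplicates_then_picks_one_year():
    preds = pd.DataFrame(
        {
            "loc_id": [1, 1, 2, 3],
            "year": [2019, 2019, 2019, 2019],
            "actual": [3.0, 3.0, 8.0, 13.0],
            "predicted": [4.0, 6.0, 8.0, 11.0],
        }
    )
    fit = evaluate_holdout(preds, seed=0)
    # duplicate (1, 2019) averages to 5; (3,5), (8,8), (13,11) are collinear
    assert fit["n"] == 3
    assert fit["slope"] == pytest.approx(0.6)
    assert fit["r2"] == pytest.approx(1.0)


def test_evaluate_holdout_matches_textbook_ols():
    actual = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    predicted = np.array([1.2, 1.9, 3.3, 3.8, 5.4])
    preds = pd.DataFrame(
        {"loc_id": np.arange(5), "year": 2019, "actual": actual, "predicted": predicted}
    )
    fit = evaluate_holdout(preds, seed=0)
    sxy = ((actual - actual.mean()) * (predicted - predicted.mean())).sum()
    sxx = ((actual - actual.mean()) ** 2).sum()
    syy = ((predicted - predicted.mean()) ** 2).sum()
    assert fit["slope"] == pytest.approx(sxy / sxx)
    assert fit["r2"] == pytest.approx(sxy**2 / (sxx * syy))


def test_evaluate_holdout_requires_points():
    with pytest.raises(ValueError):
        evaluate_holdout(pd.DataFrame(), seed=0)
    one = pd.DataFrame({"loc_id": [1], "year": [2019], "actual": [1.0], "predicted": [1.0]})
    with pytest.raises(ValueError):
        evaluate_holdout(one, seed=0)
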