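import datetime as dt

import numpy as np
import pytest

from stopover_radar.config import (
    LandscapeConfig,
    StationSpec,
    TruthModel,
    desk_default,
)
from stopover_radar.grids import Grid
from stopover_radar.scans import FLAG_VALID, PolarGeometry, PolarScan, Sweep


def make_scan(
    dbz_by_elevation: dict[float, np.ndarray],
    geometry: PolarGeometry,
    station_id: str = "T01",
    timestamp: dt.datetime = dt.datetime(2020, 1, 2, 0, 0),
    minutes_after_sunset: float | None = None,
) -> PolarScan:
    sweeps = []
    for el, dbz in sorted(dbz_by_elevation.items()):
        dbz = np.asarray(dbz, dtype=np.float32)
        flags = np.where(np.isfinite(dbz), FLAG_VALID, 1).astype(np.uint8)
        sweeps.append(Sweep(elevation_deg=el, dbz=dbz.copy(), flags=flags))
    return PolarScan(
        station_id=station_id,
        timestamp=timestamp,
        geometry=geometry,
        sweeps=sweeps,
        minutes_after_sunset=minutes_after_sunset,
    )


@pytest.fixture(scope="session")
def tiny_landscape_cfg() -> LandscapeConfig:
    return LandscapeConfig(
        domain_size_km=(96, 96), n_stations=1, grf_range_km=15.0, n_cities=6
    )


@pytest.fixture(scope="session")
def tiny_stack(tiny_landscape_cfg):
    from stopover_radar.predictors import add_andd_layers
    from stopover_radar.synth.landscape import generate_landscape

    stack = generate_landscape(tiny_landscape_cfg, seed=7)
    add_andd_layers(stack)
    return stack


@pytest.fixture(scope="session")
def tiny_truth(tiny_stack):
    from stopover_radar.synth.truth import generate_truth_density

    truth = TruthModel()
    return {
        (s, y): generate_truth_density(tiny_stack, truth, s, y, seed=7)
        for s in ("spring", "fall")
        for y in (2019, 2020)
    }


@pytest.fixture(scope="session")
def tiny_table(tiny_stack, tiny_truth):
    """Training table assembled directly from the truth surface."""
    from stopover_radar.measurement import StopoverRaster
    from stopover_radar.model import location_split
    from stopover_radar.predictors import assemble_training_table

    rasters = {
        y: StopoverRaster(
            values=tiny_truth[("spring", y)], grid=tiny_stack.grid, season="spring", year=y
        )
        for y in (2019, 2020)
    }
    stations = [StationSpec("T01", 48.0, 48.0)]
    table = assemble_training_table(rasters, tiny_stack, "spring", 2500, 7, stations)
    table["split"] = location_split(table["loc_id"].to_numpy(), 7)
    return table


@pytest.fixture(scope="session")
def tiny_model(tiny_table):
    from stopover_radar.config import BoostConfig
    from stopover_radar.model import BoxSpec, train_box_model

    spec = BoxSpec(48.0, 48.0, 96.0, 0.0, 96.0, 0.0, 96.0)
    box = train_box_model(tiny_table, spec, BoostConfig(seed=7, n_estimators=120))
    assert box is not None
    return box


@pytest.fixture(scope="session")
def desk_run():
    """One full desk-scale pipeline run (both seasons, holdout only).

    Shared by the acceptance tests; standard box training is exercised
    separately on the reduced directionality world.
    """
    from stopover_radar.pipeline import run_pipeline

    cfg = desk_default(1)
    return run_pipeline(
        cfg, seasons=("spring", "fall"), train_standard=False, run_holdout=True
    )
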