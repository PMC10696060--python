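#!/usr/bin/env python
"""Stage 2: 49-predictor training tables and the predictor-correlation check.

Samples locations from the measured coverage, attaches the 49 predictors and
the location-level train/validation/test split, writes the seasonal tables,
and runs the repeated-small-draw Pearson-correlation experiment between
skyglow and the habitat predictors it could be confounded with.
"""
import pickle
import sys
from pathlib import Path

from stopover_radar.interpret import predictor_correlation_experiment
from stopover_radar.io import save_table
from stopover_radar.pipeline import season_table
from stopover_radar.predictors import predictor_registry

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    with open(RESULTS / "cache" / "stage1.pkl", "rb") as f:
        s1 = pickle.load(f)
    cfg, stack, stations, measured = s1["cfg"], s1["stack"], s1["stations"], s1["measured"]

    tables = {}
    for season in cfg.landscape.seasons:
        table = season_table(cfg, stack, stations, measured[season], season)
        tables[season] = table
        save_table(RESULTS / f"table_{season}.csv", table, predictor_registry())
        frac = table.attrs["nonmissing_fraction"]
        worst = sorted(frac.items(), key=lambda kv: kv[1])[:3]
        print(f"{season}: {len(table)} rows ({table.attrs['n_dropped']} dropped); "
              f"least complete predictors: {worst}")

    # is skyglow confounded with the habitat predictors it competes with?
    pairs = [
        ("skyglow", "canopy"),
        ("skyglow", "lc5_deciduous"),
        ("skyglow", "lc5_water"),
        ("canopy", "lc5_deciduous"),
    ]
    corr = predictor_correlation_experiment(stack, pairs, seed=seed)
    corr.to_csv(RESULTS / "predictor_correlations.csv", index=False)
    print(corr.to_string(index=False))

    with open(RESULTS / "cache" / "stage2.pkl", "wb") as f:
        pickle.dump({"tables": tables}, f)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
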