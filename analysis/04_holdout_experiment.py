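#!/usr/bin/env python
"""Stage 4: the 10-km spatial-holdout experiment.

Reruns each small box holding out a 10-km block centered on the median of
its training locations (boxes with fewer than 25 held points are excluded),
pools predictions, averages duplicates, keeps one random year per location,
and reports the OLS fit of predicted on actual stopover density.
"""
import json
import pickle
import sys
from pathlib import Path

from stopover_radar.model import evaluate_holdout, holdout_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    with open(RESULTS / "cache" / "stage1.pkl", "rb") as f:
        cfg = pickle.load(f)["cfg"]
    with open(RESULTS / "cache" / "stage2.pkl", "rb") as f:
        tables = pickle.load(f)["tables"]
    with open(RESULTS / "cache" / "stage3.pkl", "rb") as f:
        boxes = pickle.load(f)["boxes"]

    small = [b for b in boxes if b.side_km == cfg.partition.side_small_km]
    summary = {}
    for season, table in tables.items():
        pool = holdout_experiment(table, small, cfg.holdout, cfg.boost)
        pool.to_csv(RESULTS / f"holdout_pool_{season}.csv", index=False)
        fit = evaluate_holdout(pool, cfg.seed)
        summary[season] = fit
        print(f"{season}: holdout R^2 {fit['r2']:.3f}, slope {fit['slope']:.2f}, "
              f"n {fit['n']} locations")
    (RESULTS / "holdout_summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
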