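#!/usr/bin/env python
"""Stage 5: variable importance, directionality, and category gain pooling.

For each season's box ensemble: mean normalized gain per predictor, the
partial-dependence slope-vote directionality class for every predictor, and
the percent of pooled gain per predictor category (distance to radar and
year excluded). Writes CSVs and, if matplotlib is present, a top-10
importance bar chart.
"""
import pickle
import sys
from pathlib import Path

from stopover_radar.interpret import (
    category_gain_summary,
    directionality_table,
    mean_gain,
)
from stopover_radar.predictors import predictor_registry

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    with open(RESULTS / "cache" / "stage3.pkl", "rb") as f:
        models = pickle.load(f)["models"]

    for season, fitted in models.items():
        small = [m for m in fitted if m.spec.side_km == min(b.spec.side_km for b in fitted)]
        table = directionality_table(small)
        table = table.sort_values("mean_gain", ascending=False)
        table.to_csv(RESULTS / f"directionality_{season}.csv", index=False)
        gains = mean_gain(small)
        cats = category_gain_summary(gains, predictor_registry())
        cats.sort_values(ascending=False).to_csv(
            RESULTS / f"category_gain_{season}.csv", header=["pct_of_gain"]
        )
        top = table.head(10)[["variable", "mean_gain", "pct_positive", "classification"]]
        print(f"--- {season}: top-10 predictors by mean gain ---")
        print(top.to_string(index=False))
        sky = table[table["variable"] == "skyglow"].iloc[0]
        print(f"{season}: skyglow class={sky['classification']} "
              f"({sky['pct_positive']:.0f}% of significant slopes positive)")
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 4))
            colors = {"positive": "#2166ac", "negative": "#b2182b"}
            ax.barh(
                top["variable"][::-1], top["mean_gain"][::-1],
                color=[colors.get(c, "0.6") for c in top["classification"][::-1]],
            )
            ax.set_xlabel("mean gain")
            ax.set_title(f"Top-10 predictors, {season}")
            fig.tight_layout()
            fig.savefig(RESULTS / f"importance_{season}.png", dpi=150)
            plt.close(fig)
        except ImportError:
            pass


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
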