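# stopover-radar

Continental-scale mapping of nocturnal bird-migration **stopover density**
from weather-surveillance radar, re-implemented as a tested Python pipeline
and exercised end-to-end on a synthetic radar + landscape world with known
ground truth.

During spring and fall migration, billions of songbirds take off from
terrestrial stopover sites shortly after sunset. The low-elevation sweeps of
S-band weather radars capture this exodus: vertically integrated linear
reflectivity (η, cm²/km²) at the nightly take-off instant is a proxy for the
density of birds departing each ground pixel. Turning that signal into
seasonal 1-km maps — and into an understanding of what drives stopover use
(forest cover, skyglow, precipitation, thermal time, ...) — requires a long
chain of radar quality control and a spatially careful niche model. This
package implements that chain for researchers in radar aeroecology and
macroecological distribution modelling:

- **Clutter mitigation** — terrain beam-blockage masks under 4/3-earth
  refraction; static clutter from multi-year probability of detection
  (POD ≥ 20% at 10 dBZ in ≥ 2 years of January clear scans); precipitation
  masking with 5-km ground-distance dilation and 30% scan rejection.
- **Exodus-time selection** — a penalized GAM of median η on minutes after
  sunset (k = 10, date intercept offsets); the steepest predicted rise
  defines each station's sampling instant.
- **Range correction** — a vertical profile of reflectivity (0–2000 m AGL,
  100-m bins) corrects partial beam overlap; adjustment factors are capped
  at 10 and coverage at 7.5–80 km; nightly maps are averaged per season and
  mosaicked across stations.
- **Niche model** — 49 predictors; gradient-boosted regression trees
  (max_depth 16, learning rate 0.1, early stopping) trained inside
  randomly placed spatial bounding boxes to prevent long-distance learning,
  with a location-level 75/15/10 split, mosaicked prediction at a fixed
  35-km distance-to-radar, and a 10-km spatially separated holdout
  experiment.
- **Interpretation & mapping** — mean gain, partial-dependence slope-vote
  directionality (>55% positive / <45% negative), category gain pooling,
  265-km focal-window hotspot classes, seasonal difference surfaces, and
  flyway summaries.
- **Synthetic world** — a first-class generator for landscape predictors,
  a known lognormal truth density (signal sd 1.0, noise sd 0.2), and polar
  radar scan series with logistic take-off dynamics, ground clutter,
  precipitation, and optional bat rings — so every stage is testable
  without touching real archives.

## Worked example

Run the desk-scale study (512 × 512 km, 9 stations, 2 years) end to end:

```python
from stopover_radar import desk_default
from stopover_radar.pipeline import run_pipeline

products = run_pipeline(desk_default(seed=1), seasons=("spring",),
                        train_standard=False)
print(products["spring"]["exodus_min"])
print(products["spring"]["holdout"])
```

prints (abridged) the per-station exodus times recovered from the scan
series, e.g.

```
{'S01': 73.0, 'S02': 31.0, 'S03': 71.0, ..., 'S09': 54.0}
```

— each within a couple of minutes of the take-off midpoints the simulator
planted in [27, 77] min (mean absolute error 1.5 min) — and the pooled
spatial-holdout fit

```
{'r2': 0.928, 'slope': 0.815, 'intercept': 11.96, 'n': 204}
```

meaning that models trained with a 10-km block spatially excluded still
explain ~93% of the variance in measured stopover density at the held-out
locations (the fall-configured run, with its 1.66× seasonal density scale,
reaches R² = 0.955 over 278 locations). Across the trained ensemble,
skyglow carries the largest mean gain and is classified positive in 100%
of models with a significant partial-dependence slope — recovering the
planted +0.8 standardized coefficient — while cultivated-crop cover
classifies negative, matching its planted sign. The numbered drivers under `analysis/` run the same stages as a
narrative (simulate → predictors → train/predict → holdout → interpretation
→ maps), writing rasters, tables and summaries under `results/`.

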