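# blocksdm

Bias-aware species distribution modelling (SDM) for presence-only
occurrence data on gridded environmental layers.

Citizen-science records of invasive plants — the motivating case is a
large hogweed-type invader spreading across a continental study area —
carry strong *sampling bias*: record density tracks where observers live,
not where the species thrives. `blocksdm` implements a complete,
reproducible pipeline that confronts this bias at every stage:

1. **Spatial thinning** — enforce a minimum nearest-neighbour distance
   (presets 4 / 7 / 10 km) between retained records by randomised greedy
   pruning of the proximity graph, repeated (default 100 iterations) and
   keeping the best iteration, approximating the maximum independent set.
2. **Pseudo-absence generation** — a combined *disk* strategy (background
   points at least 25 km from every presence, optionally drawn with the
   same sampling bias as the presences) and a *filtered random* strategy
   (points north of a latitude threshold, default 64°, where the species
   is physiologically excluded).
3. **Feature selection** — Pearson correlation grouping at |r| ≥ 0.8, then
   Mean Decrease Gini (MDG) and Mean Decrease Accuracy (MDA) random-forest
   importance; each correlated group is resolved to one representative,
   with cross-validated AUC breaking ranking disagreements. Every decision
   is written to an audit log.
4. **Spatial-block cross-validation** — square 100-km blocks assigned
   randomly to k = 13 folds, repeated 20 times, scoring tie-aware ROC-AUC
   `(concordant + ½·tied) / (n₊·n₋)`; blocks, not points, cross the
   train/test boundary, removing the optimism that spatial autocorrelation
   lends to random splits.
5. **Suitability projection** — the final forest is projected cellwise over
   present and substituted future climate stacks (soil layers carried over
   unchanged), and maps are summarised by reporting bands
   (fraction of territory with p < 0.25 and p > 0.5), mean/max suitability,
   and within-block variability.

A first-class **synthetic-data generator** builds study systems with known
truth — spatially autocorrelated covariate rasters (BIO1–BIO19 plus five
soil properties) with planted correlated pairs, a logistic true-suitability
surface, a cold northern strip, and effort-biased presence sampling — so
every claim the pipeline makes is testable against ground truth.

## Worked example

```python
import numpy as np
import blocksdm as b

world = b.make_world(seed=0)                                  # 60x60 cells, 24 covariates
pts = b.sample_presences(world.truth, world.bias, 2000, seed=100)

res = b.thin(pts, distance_km=7.0, iterations=10, seed=200)
print(f"retained {res.n_retained}/2000 records at 7 km")

occ, feat = b.assemble_training_set(
    pts[res.retained],
    b.PseudoAbsenceConfig(seed=300, effort=world.bias),        # bias-matched disk PAs
    world.stack,
)
sel, audit = b.select_features(feat, occ.labels, seed=400, points=occ.points)
folds = b.make_folds(occ.points, block_km=100, k=13, repeats=5, seed=500)
cv = b.cross_validate(feat[sel], occ.labels, folds, seed=500)
model = b.fit_final_model(feat, occ.labels, sel, seed=600)
smap = b.project(model, world.stack)

ok = ~smap.grid.mask
print(f"block-CV AUC {cv.auc_mean:.3f}")
print(f"map vs truth r = {np.corrcoef(smap.grid.values[ok], world.truth.values[ok])[0,1]:.3f}")
```

On this seed the run prints:

```
retained 1617/2000 records at 7 km
block-CV AUC 0.948
map vs truth r = 0.805
```

Thinning removes roughly a quarter of the records (the clustered excess
near the synthetic population centres); the block-CV AUC is the honest
spatial estimate of discrimination; and the projected map recovers the
planted niche surface at r ≈ 0.76 despite the sampling bias.

A command-line interface mirrors the stages
(`blocksdm simulate | thin | background | select | cv | fit | predict |
summarize | run-all`); point tables are plain CSV (`lon,lat[,label,source]`)
and rasters are ESRI ASCII grids.

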