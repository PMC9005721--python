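# Methods

## The modelling problem

`blocksdm` addresses presence-only species distribution modelling under
sampling bias. The data are (i) occurrence records as lon/lat points
(WGS84) and (ii) a stack of header-aligned environmental rasters in ESRI
ASCII format — 19 bioclimatic variables (BIO1–BIO19) plus soil properties
(Silt, Sand, CF, CEC, SOC) in the intended application. The model is a
binary random-forest classifier trained on presences versus generated
pseudo-absences; its cellwise positive-class probability is read as a
habitat-suitability score in [0, 1].

Because the records come from citizen-science sources, their density
reflects recording effort as much as habitat quality. The pipeline
therefore combines two mitigations: spatial thinning of the presences and
pseudo-absences constructed to carry either no spatial preference (uniform
disk strategy) or the same effort bias as the presences (effort-weighted
disk strategy), plus an expert-knowledge "filtered random" stratum of
absences in the far north. Evaluation uses spatial-block cross-validation
so that spatial autocorrelation cannot leak across the train/test split.

## Geometry

Distances between records are exact haversine great-circle distances on a
sphere of radius 6371.0 km. Block tilings for cross-validation and map
variability live in a local equirectangular projection
(x = Δlon·111.195·cos lat_ref, y = Δlat·111.195, lat_ref = the point
cloud's mid-latitude) with half-open square cells and a floor convention,
so every point belongs to exactly one block and blocks are metrically
near-square over a mid-latitude extent. Thinning and the pseudo-absence
exclusion radius deliberately use the exact haversine rather than the
block projection, since those constraints are stated in kilometres
between points.

Raster cells follow the row-0-north convention; point-in-cell containment
is half-open, closed on the west and north edges, which makes extraction
deterministic for boundary points. A point invalid for one layer (outside
the extent or on NODATA) is invalid for all layers — one shared validity
decision per point. Stacking requires bitwise-equal header geometry; no
resampling is implemented, as inputs are assumed pre-unified to a single
grid.

## Thinning

`thin(points, distance_km, iterations, seed)` builds the proximity graph
(edges between points closer than the distance) and repeatedly removes a
uniformly random point among those of maximal degree until no edges
remain. The procedure repeats `iterations` times (default 100) with
independent randomisation; the iteration retaining the most points wins
(first achieved on ties). This is a randomised greedy approximation to
the maximum independent set; on instances small enough for exhaustive
search (n ≤ 14) the best-of-100 result matches the exact optimum in
≥ 95% of random instances (verified in the test suite). Preset distances
are 4, 7 and 10 km.

## Pseudo-absences

`PseudoAbsenceConfig` defaults: one pseudo-absence per presence (1:1
balance keeps AUC interpretable; exposed in config), half from the disk
strategy and half from the filtered random strategy (`disk_fraction`
0.5), a 25-km exclusion radius, and a 64°N latitude threshold for the
random stratum.

The disk strategy rejection-samples cell-jittered points over the
unmasked domain and accepts those at least `min_dist_km` from every
presence, raising an infeasibility error (never a silent short count)
after 1000·n proposals. With an `effort` grid supplied, proposal cells
are drawn proportionally to it, giving the background the same sampling
bias as the presences so that effort cancels in the presence/background
contrast. The filtered random stratum samples uniformly over unmasked
cells lying entirely north of the threshold. The disk constraint is
applied to the thinned presence set (the modelling dataset).

## Feature selection

Stage one groups covariates into connected components of the graph with
edges where |Pearson r| ≥ 0.8 over training rows (zero-variance columns
are excluded with a warning). Stage two ranks all variables by MDG
(the forest's impurity-based importance) and MDA. MDA is defined here as
the mean drop in accuracy on an internal stratified 25% held-out split
when a column is permuted, averaged over 10 permutations; a held-out
split is used rather than out-of-bag samples because the installed
forest implementation exposes no public per-tree OOB indices, and the
two estimators target the same quantity.

Selection keeps each singleton ranked in the top half by MDG *or* MDA,
and resolves each multi-member group to one representative: the member
best by both rankings when they agree, otherwise the best-by-MDG and
best-by-MDA contenders are compared by refitting one candidate model per
contender (the group's other members excluded) and keeping the higher
cross-validated AUC — spatial-block CV when coordinates are available.
The numeric "top half" rule is this package's own concretisation of
"highly important"; since any such cut is somewhat arbitrary, every
kept/dropped decision is emitted in a JSON audit log, and a manual
variable list can override selection entirely through the pipeline
config.

## Cross-validation and AUC

Blocks of 100 km edge are assigned uniformly at random to k = 13 folds,
independently for each of 20 repeats (all defaults config-exposed). If an
assignment leaves a fold empty, one block is moved from the largest fold,
preserving k-fold semantics on small synthetic domains. Folds where the
training or test side contains a single class are recorded as skipped,
never imputed. AUC is tie-aware, computed by the Mann–Whitney rank
identity, and equals the brute-force pairwise count exactly. The
aggregate is the unweighted mean (and sd) over defined fold × repeat
cells.

Random-forest defaults: 500 trees, √p features per split, unlimited
depth, plain bootstrap, fixed seed. Heavier experiments in the test suite
and the acceptance script use 100–300 trees; this changes Monte Carlo
noise, not the estimator's structure, and problem sizes are stated with
each experiment.

## Projection and map summaries

The final forest is fitted on all assembled rows restricted to the
selected variables and projected cellwise over any stack containing
them; future stacks carry the soil layers over unchanged, on the
assumption that soil properties are stable over the forecast horizon.
Summaries report the fractions of unmasked cells with p < 0.25 and
p > 0.5 (the reporting bands used throughout), the mean and maximum
suitability, and block variability — the mean over 100-km blocks of the
within-block population standard deviation of cell predictions, computed
on cell centres. The three bands partition the unmasked cells exactly.
`compare_thinnings` runs the downstream pipeline once per thinned
dataset and flags the distance maximising block variability as its
suggested choice; this is one operationalisation of "most spatially
diverse prediction", not a claim of uniqueness.

## The synthetic study system

`make_world` generates the benchmark world all tests run against:

- **Domain** — a 30° × 30° box (lon 30–60, lat 40–70) at 0.5° resolution,
  60 × 60 cells: a toy-scale analogue of a continental mid/high-latitude
  study area on which every experiment runs in seconds.
- **Covariates** — 19 BIO-like plus 5 soil-like layers of Gaussian-blurred
  white noise standardised to mean 0, sd 1. The default blur of 3 cells
  (~150–200 km) mimics continental-scale autocorrelation of climate
  surfaces. One planted correlated pair, BIO11 = BIO1 + scaled noise with
  empirical |r| ≥ 0.85, mirrors the redundancy of real bioclim layers.
- **Truth** — logistic(−0.3 + 2.0·BIO1 − 1.5·BIO13 + 1.2·SOC): two
  bioclim-like and one soil-like informative variable. The temperature
  effect is positive — a species limited at its cold range edge — so a
  warming scenario moves the cold strip toward the niche optimum. The
  magnitudes give a clear niche signal; a benchmark whose signal cannot
  be recovered even by an oracle model would validate nothing.
- **Cold strip** — the northern 20% of rows has truth multiplied by 0.02,
  a tundra-like zone beyond the species' physiological limit that the
  covariates do not encode; the latitude-filtered pseudo-absences are
  what allows a model to learn it.
- **Sampling effort** — five fixed "population centres" with exponential
  decay (default 50 km) plus 1% of the peak as diffuse background effort
  (roads and villages generate occasional records everywhere; with zero
  floor most of the domain would be entirely unobserved and no method
  could map it). Presences are drawn per cell with probability
  proportional to truth × effort and jittered uniformly within the cell,
  so records are not cell-centred.
- **Future stacks** — additive warming of the temperature-like layers
  (BIO1–BIO11) by a chosen multiple of each layer's sd, optionally
  restricted to a row band; soil layers pass through unchanged. No
  climate-model physics is emulated; future stacks are opaque named
  inputs to the projection stage, exactly as in the real workflow.

What the generator does *not* emulate: interactions or non-monotone
niche responses, coastline/NODATA geometry, temporally varying effort,
taxonomic misidentification, and GPS error beyond cell jitter. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its bias mitigations work when the bias matches the
effort-decay model — not that any real dataset is free of other
artefacts.

## Numerical and degenerate-input choices

NODATA comparison is exact float equality with the header sentinel, per
the format's contract. ASCII output uses repr-precision numbers, making
read∘write lossless to better than 1e-6 relative. Empty thinning input
returns an empty result; non-positive distances, single-class labels,
fully masked maps, infeasible pseudo-absence constraints, and fewer
blocks than folds all raise explicit errors. All stochastic stages take
a seed; the pipeline derives per-stage seeds from one global seed by
fixed offsets, so a rerun with the same config is seed-reproducible.

## Experiment sizes

The validation experiments use deliberately modest sizes so the whole
suite runs on one CPU in minutes: worlds of 60 × 60 cells, 2000 biased
presences (300–1500 for CV-focused checks), 10-iteration thinning inside
multi-seed experiments (100 where optimality itself is under test),
100–300 trees inside loops, and 2-seed model averaging in the
thinned-versus-unthinned comparison to suppress forest Monte Carlo noise.
The bias-mitigation claim is evaluated over 20 seeded worlds; feature
recovery over 10.

## Known limitations

- The thinning heuristic is near-optimal, not exact, for large n.
- The top-half importance cut is a pragmatic rule; on worlds where
  sampling bias genuinely confounds the weakest informative variable
  (2 of 10 benchmark seeds), selection can drop it — the audit log makes
  such cases inspectable.
- Suitability scores are case-control probabilities under the chosen
  presence:pseudo-absence ratio, not calibrated prevalence; maps are
  comparable across scenarios but not absolute probabilities of
  occurrence.
- Block variability as a thinning-distance selector is a heuristic
  diagnostic, and the equirectangular block tiling distorts at extreme
  latitudes.
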