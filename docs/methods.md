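# Methods

## The problem

Shallow groundwater can raise rainfed maize yields by supplying water
during climatic deficits — a *groundwater yield subsidy* — or depress them
by waterlogging the root zone when the water table is very shallow — a
*yield penalty*.  The package implements the inferential machinery for
detecting and quantifying these effects from gridded cell-year (or
pixel-year) records of yields, July depth-to-water, weather and soils:

1. fit a bagged-tree surrogate of yield on the covariate panel;
2. trace the accumulated-local-effects (ALE) response of yield to July
   depth-to-water;
3. read the curve: a flat terminal plateau at deep water tables is the
   free-drainage baseline, the maximum above it the optimum, the interval
   where the curve exceeds the baseline the subsidy zone, and depths
   shallower than the zone the penalty regime;
4. quantify attenuation under covariate error, the direct/capillary
   mechanism split, yield-stability effects, and the prevalence and
   monetary value of subsidy/penalty conditions.

Because no external data ship with the package, a synthetic world with a
*known, injected* groundwater effect drives every analysis; each stage is
validated by parameter recovery against that truth.

## The injected effect

For depth-to-water `d` (m, positive downward) and July water deficit `w`
(mm, precipitation − PET):

```
effect(d, w) = A(w) · s_max · bump(d)  −  p · max(0, d_low − d)
```

* `bump` is a raised cosine: zero at `d_low` and `d_high` with zero slope,
  1 at `d_opt` (piecewise on either side of the optimum, so the optimum
  need not sit mid-zone).  Defaults `d_low = 1.1`, `d_opt = 1.5`,
  `d_high = 2.5` m; the effect is exactly zero at and beyond `d_high`
  (free drainage).
* `A(w)` is 1 except in very dry Julys (`w < −150` mm) where it equals
  `drought_amplifier` (default 2): groundwater is worth most when the
  deficit binds.
* `p` is the waterlogging penalty slope (default 0.45 t/ha per m), linear
  below `d_low`; wet Julys do not worsen it.
* `s_max` defaults to 0.37 t/ha (≈ 3.4 % of the ~10.8 t/ha mean yield).

## The synthetic world

One record per cell-year (grain `"grid"`), or several noisy yield
replicates per cell-year sharing the cell's *recorded* groundwater value
while responding to a latent pixel-level depth (grain `"pixel"` — the
resolution mismatch the attenuation analysis studies).

Structure, per cell: a site mean depth uniform on [0.3, 6.0] m (so the
depth axis covers penalty, subsidy and free-drainage regimes), AR(1)
interannual anomalies (ρ = 0.45), and a weather coupling of 0.5 m per
100 mm of deficit anomaly — water tables deepen in dry years, giving the
negative depth–deficit correlation real systems show.  Tile-drained cells
(30 %) never report depths shallower than the 1.0 m drain depth.  July
deficits combine a persistent site-dryness component, a regional year
effect and cell-year noise (mean −65, SD 65 mm), populating all four
weather classes (≈ 60 % of cell-years drier than −50 mm, ≈ 10 % drier than
−150 mm).  VPD is high at persistently dry sites and in dry years, which
is what makes VPD terciles informative for the stability analysis.

Yields are a concave base response (declining once the deficit passes
−50 mm) plus soil and soil-moisture terms, the injected effect, and
Gaussian noise.  Noise levels are calibrated against the out-of-bag
diagnostics the surrogate should reproduce: 0.25 t/ha at the grid grain
(OOB R² ≈ 0.90) and 0.75 t/ha at the pixel grain (≈ 0.7).

### The two soil-moisture variants and the mechanism wiring

`sm_standard` is top-down plant-available moisture in the top 1 m (mean
70 mm, driven by the deficit, soils and noise).  `sm_enhanced` adds a
capillary increment that rises monotonically as the water table shallows,
vanishing at `d_high` (the fringe no longer reaches the root zone), with
mean-one lognormal record-level delivery noise (σ = 0.5) and a scale
calibrated so the median relative boost within reach is 30 %.

Yield values capillary moisture at the same coefficient as top-down
moisture — the identity that makes the covariate swap identify the
mechanism — and that coefficient is calibrated so the channel's mean
contribution at `d_opt` is exactly `1 − direct_share` of the subsidy
there; the structural direct term is the remainder, keeping the
conditional-mean total equal to `effect(d, w)` everywhere.  Two earlier
designs fail and are worth recording: valuing capillary moisture at a
*different* rate than top-down moisture lets a flexible model reconstruct
`sm_standard` from (`sm_enhanced`, depth) and contaminates the depth
effect; and making the increment proportional to the *bump shape* makes
`sm_enhanced` a near-proxy of the direct effect, so trees absorb the
direct share through it.  A monotone reach profile avoids both.

### What the generator does not emulate

No mechanistic water balance, no spatial autocorrelation between cells, no
trends or technology drift, no measurement bias structure beyond additive
noise, no price–production feedback.  Passing recovery tests therefore
shows the *inference machinery* is sound under the statistical structure
the study describes — not that the method is robust to, say, spatially
correlated confounding that real landscapes can harbour.

## The surrogate

Random forest regression (scikit-learn) with the study hyperparameters:
100 trees, 6 candidate variables per split, node-size 10, evaluated
out-of-bag (R² reported as 1 − MSE_oob/var(y), the variance-explained
convention).  Node size follows the semantics of the R `randomForest`
implementation, verified empirically against it: a node with ≤ 10 cases
becomes terminal, so terminal nodes can be much smaller
(`min_samples_split = 11`, `min_samples_leaf = 1`).  Mapping node size to
a *leaf* minimum instead over-smooths the fitted surface and attenuates
the recovered subsidy noticeably.

Groundwater-period screening is greedy forward selection over the May–
August and annual depth columns on held-out MSE (hold-out split by cell),
keeping a candidate only if it improves MSE by > 2 % relative — above the
hold-out noise floor at typical table sizes, well below the gain from a
real groundwater period.  A
spline-based screener would do the same job; the selection outcome, not
the selector, is what downstream stages consume.

## The ALE estimator

First-order ALE, written here from scratch: quantile bins (default
`k_bins = 40`; duplicate edges merged, empty bins pooled), per-observation
prediction differences across each bin, accumulated by cumulative sum,
centered by the count-weighted mean of bin-midpoint effects (so the
count-weighted mean of the interpolated curve is 0 within 1e−8).  Bin
membership is `(lower, upper]` with the lowest edge included in bin 0.
Bootstrap bands resample *cells* (cluster bootstrap, default B = 500),
refit the surrogate per resample, interpolate each resampled curve onto
the point curve's edges and take percentile 2.5/97.5 envelopes, anchored
to contain the point estimate.  The band gates subsidy detection
conservatively: a subsidy is called only when the band's lower edge at the
optimum exceeds the *upper* envelope of the baseline (count-weighted over
the plateau).  Comparing against the point baseline instead false-detects
in null worlds at small samples, because the optimum is itself selected as
the argmax of a noisy curve.

## Zone delineation

Numerical choices, all surfaced in `StageOptions` and logged in run
manifests:

* Plateau scan from the deep end: the longest terminal run of per-edge
  slopes within `slope_tol = 0.05` t/ha per m, at least
  `min_plateau_width = 0.8` m wide.  Slopes are measured on a 3-edge
  moving average of the curve — single-bin estimation noise otherwise
  breaks an honestly flat plateau — while effect values themselves are
  never smoothed.  A tolerance much below 0.05 is under the slope noise
  floor of a 40-bin forest ALE curve and finds no plateau at realistic
  sample sizes.
* Baseline = count-weighted mean of bin-midpoint effects over the plateau;
  the onset depth is the plateau's shallow end.
* Optimum = argmax over edges shallower than the onset, refined by a
  3-point parabola (the curve is sampled at bin edges, so the raw argmax
  is biased low for a peak between edges).
* Subsidy-zone shallow bound = baseline crossing nearest the optimum,
  linearly interpolated between edges; with multiple noisy crossings this
  is the conservative (narrowest-zone) choice.
* When a curve has lost its plateau (noisy covariates do this), an
  external `baseline_region` — typically the clean run's onset — can be
  supplied; the report keeps `baseline_found = False` so the fallback is
  visible.
* Penalty magnitude is quoted at the mean observed depth within the
  penalty zone, as a fraction of mean yield.

## Experiments

*Attenuation.*  `x' = x + ε`, `ε ~ N(0, sd(x)·sqrt(1/r² − 1))`, truncated
at zero.  Covariate noise flattens the whole response curve, so freely
re-delineating the degraded curve is meaningless (it finds spurious,
overlong plateaus); instead clean and noisy curves are both read in the
clean run's geometry — peak effect shallower than the clean free-drainage
onset minus the mean effect beyond it — and shrinkage is their ratio
(reported raw; small negative values mean the subsidy is undetectable
under that noise).  For a linear injected effect the comparison statistic
is the central weighted-LS slope of the curve, where classical
errors-in-variables theory predicts shrinkage r².  The pixel grain needs
no injected noise: the recorded cell-level depth is already an erroneous
measure of the latent pixel depth.

*Mechanism.*  Two fits sharing seed and covariates except the
soil-moisture column (`sm_standard` vs `sm_enhanced`); the indirect share
is `1 − effect_B/effect_A` at run A's optimum, both effects read by linear
interpolation against their own baselines over a common free-drainage
region, clipped to [0, 1] (clipping logged).  A zone-integrated variant is
available but non-default.

*Stability.*  Per-location CV of yields across years (sample SD, n−1),
locations with ≥ 5 years; a forest of CV on location-level covariates
(mean depth, mean VPD, soils, drainage, tile status); ALE of CV against
mean July depth overall and within terciles of location-mean VPD (tercile
sizes differ by ≤ 2; boundary ties broken by location id).  CV curves use
coarser bins than yield curves (broad trend, small location tables), and
the shallow-vs-deep CV gap averages each endpoint over a 0.6 m depth
window to damp single-bin noise.  Nothing in the generator encodes CV: any
depth–CV relationship is emergent, arising only because the
(drought-amplified) subsidy offsets dry-year losses.

*Prevalence and accounting.*  Boundary conventions: zone membership is the
closed interval [subsidy_low, subsidy_high]; penalty is strictly shallower
than the penalty threshold (so penalty and access are disjoint); dry means
deficit < −50 mm, very dry < −150 mm.  A very-dry coincidence year uses
the strong-subsidy rate *instead of* the plain rate, never both.  Default
effect percentages (−1 %, 3.4 %, 7.8 % of production value) are config
inputs.  Weather-class boundary ties: 0 and −50 mm fall to *normal*,
−150 mm to *dry*; the classes partition the deficit axis.

## Reproducibility and problem sizes

One master seed; per-stage child seeds derived via `SeedSequence` spawn
keys; identical (config, seed) reproduce bit-identical tables and
manifests.  The recovery experiments run at desk scale, chosen so each
completes in minutes on one CPU while leaving the estimators comfortably
identified: zone recovery at 2,000 cells × 20 years (10 seeds), mechanism
and attenuation at 800 × 12, null calibration at 200 × 10 with 12
bootstrap resamples, stability at 2,500 cells × 20 years × 3 pixels
(7,500 locations).  Sample sizes are stated alongside every reported
quantity.

## Known limitations

* The recovered subsidy amplitude is attenuated ~10–20 % relative to the
  injected truth even with a perfectly measured covariate — tree-ensemble
  smoothing of a localized bump; the zone bounds and optimum are far less
  affected.  This mirrors the dilution the method itself studies, and is
  why magnitude comparisons in the experiments are always ratios of
  like-estimated quantities.
* The mechanism split is defined (and injected) at the optimum only;
  away from the optimum the direct/indirect decomposition of the synthetic
  world is structural, not physical.
* CV is computed without detrending; with trending yields it would
  conflate trend and variability.
* Monetary accounting prices realized production at face value: no
  inflation machinery, no prevented-planting or early-season losses.
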