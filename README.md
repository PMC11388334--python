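# gwyield

Inference of **groundwater yield subsidies and penalties** for rainfed
maize from gridded cell-year records: water tables shallow enough for
roots (or the capillary fringe) to reach supply extra water in dry Julys
and raise yields; water tables near the surface waterlog the root zone and
depress them.  The package detects both regimes, quantifies their
magnitude, prevalence and dollar value, and ships a synthetic data
generator with a *known injected effect* so the whole chain is testable by
parameter recovery — no external data required.

Who it is for: agroecosystem modellers and environmental biostatisticians
who want yield-response-curve inference over a groundwater gradient
(rather than a regression coefficient), with honest treatment of covariate
error and model-interpretation artefacts.

## The method

For yield *y*, July depth-to-water *d* (m), and a covariate panel **x**
(July water deficit P − PET, VPD, soils, tile drainage, top-down soil
moisture), fit a bagged-tree surrogate *f̂(d, **x**)* (random forest: 100
trees, 6 variables per split, node size 10, evaluated out-of-bag) and
compute the first-order **accumulated local effects** curve

&nbsp;&nbsp;ALE(d) = Σ<sub>bins ≤ d</sub> E[ f̂(z<sub>k</sub>, **x**) − f̂(z<sub>k−1</sub>, **x**) | d ∈ bin k ] − centering,

which is robust to the strong depth–weather correlation that breaks
partial-dependence plots.  The curve is read as:

* **free-drainage baseline** — the flat terminal plateau at deep *d*;
* **optimum** d<sub>opt</sub> — the effect maximum above the baseline;
* **subsidy zone** [d<sub>low</sub>, d<sub>free</sub>] — where the curve
  exceeds the baseline (injected truth: 1.1–2.5 m, optimum 1.5 m);
* **penalty zone** — depths shallower than d<sub>low</sub>.

On top of that sit four analyses: regression-dilution (degrade *d* to a
target correlation *r* with truth and measure subsidy shrinkage ≈ r² for a
linear effect), a direct-uptake vs capillary-rise **mechanism split** via a
soil-moisture covariate swap, **yield stability** (CV of yields per
location against mean depth, by VPD tercile), and **prevalence/monetary
accounting** of penalty, access, and subsidy-coincidence conditions.

## Worked example

```python
from gwyield import GroundwaterYieldModel, SimConfig

cfg = SimConfig(n_cells=2000, n_years=20, seed=11)   # injected optimum 1.5 m, zone 1.1-2.5 m
model = GroundwaterYieldModel.from_simulation(cfg)
results = model.fit(seed=11)
print(results.summary())
```

```
Groundwater yield response — surrogate + ALE fit
====================================================
observations:             40000
depth variable:      wt_depth_jul
screened periods:    (none)
OOB R2:                   0.898
OOB MSE (t/ha)^2:         0.075
mean yield (t/ha):        10.68
----------------------------------------------------
free-drainage onset d_free (m):      2.72
baseline effect (t/ha):            -0.026
optimum depth d_opt (m):             1.56
subsidy zone (m):                [1.03, 2.72]
max subsidy (t/ha):                 0.310
max subsidy (% of mean yield):       2.91
penalty threshold (m):               1.03
penalty at mean zone depth (%):      1.33
subsidy detected:                    True
```

The fitted surrogate explains ~90 % of out-of-bag yield variance; the
recovered optimum (1.56 m) and zone bounds (1.03, 2.72 m) sit within the
estimator's resolution of the injected truth (1.5; 1.1, 2.5 m), and the
maximum subsidy of 0.31 t/ha (2.9 % of mean yield) is an attenuated read
of the injected 0.37 t/ha — tree ensembles smooth localized bumps, the
same dilution phenomenon the attenuation module studies deliberately.

Downstream analyses hang off the same objects:

```python
results.stratified_effects()          # per weather-class curves (drought doubling)
from gwyield import run_attenuation_experiment, mechanism_split, stability_analysis
```

A `gwyield` CLI wraps the pipeline (`simulate`, `fit`, `zones`,
`attenuate`, `mechanism`, `stability`, `prevalence`, `report`, `all`) over
a TOML config, writing CSV/Parquet/JSON artifacts plus an auditable
manifest per run directory:

```bash
gwyield all --seed 7 --out runs/demo
```

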