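# Methods

## The model

`phenoselect` predicts the four developmental phases of a winter cereal
(sowing–emergence, emergence–jointing, jointing–heading,
heading–senescence) from daily environmental covariates, and selects
among candidate models so that the chosen model is robust not only to
phenology-model error but also to the imperfections of climate-scenario
input data.

### Dose-response curves

The elementary building block is a dose-response curve (DRC): a function
`f(x; θ)` mapping a daily covariate value `x` (temperature, global
radiation, relative humidity, vapor pressure deficit, standardized
precipitation index) to a unitless daily development increment.  Four
families are implemented:

| family | parameters | shape |
|---|---|---|
| linear | intercept, slope | unbounded, may be negative |
| broken stick | Ψ_base, slope | zero below Ψ_base, then linear |
| asymptotic | Ψ_base, lrc, Asym | saturating, clipped at zero |
| Wang–Engel | Ψ_base, Ψ_opt, Ψ_max, r | zero outside (Ψ_base, Ψ_max), maximum r at Ψ_opt |

The Wang–Engel shape exponent is
`α = ln 2 / ln((Ψ_max − Ψ_base)/(Ψ_opt − Ψ_base))`.  Evaluated exactly
at Ψ_base or Ψ_max the response is 0 (the open-interval convention);
with Ψ_base = 0 and slope 1 the broken stick reduces to classical
growing-degree-day accumulation.

The accumulated dose over a phase window is
`Z = Σ_d f(x_d; θ)` with a **half-open** day window `[start, end)` so
chained phases never count a boundary day twice.

For the temperature covariates (tasmin, tas, tasmax) and radiation only
the bounded Wang–Engel family is calibrated — temperatures beyond the
optimum must not inflate predicted development under warming — while
relative humidity, SPI and VPD are offered all four families: 16
covariate-family candidates per phase.

### Calibration

The calibration objective for a single covariate×phase is duration RMSE
under a *median required dose*: candidate parameters define each
training environment's dose at its observed phase end; the median of
those doses is the common requirement; the predicted duration is the
day the cumulative dose reaches it, **linearly interpolated between
days** so the objective is continuous rather than a staircase (a purely
numerical choice; observed durations remain whole days).  Environments
that never reach the requirement are censored at the search horizon
(twice the longest observed duration), and an all-zero dose field maps
to a large finite sentinel so derivative-free search can recover.

Optimization is a two-step constrained local search with COBYLA:

1. *coarse*: from quantile starting values (0.05/0.5/0.95 of the
   observed covariate for parameters in covariate units; slope 1,
   intercept 0, Asym 1, lrc 0, r 1 otherwise) inside quantile-derived
   bounds, ≤ 500 evaluations, relative tolerance 1e-2;
2. *fine*: restart at the coarse optimum with per-parameter bounds
   `[v − |v|, v + |v|]` (a zero-valued optimum is widened to ±0.1),
   ≤ 1000 × (number of parameters) evaluations, relative tolerance 1e-8.

Internally each parameter is divided by a quarter of its bound width
before entering the optimizer, so one trust-region step moves every
parameter by a comparable fraction of its admissible range regardless
of units (degrees vs. J/cm²) — without this the radiation curves
converge an order of magnitude slower.

Robustness comes from an ensemble of 20 such fits, each on a seeded
random 80 % subsample of the training environments (64 % of all data
after the 80/20 stratified train/validation split); the elementwise
median of the ensemble members is the final estimate.  Failed runs are
dropped, not retried, and their count is recorded; more than half
failing aborts the calibration.  Per covariate the family with the
highest Pearson correlation between observed and modelled durations
wins; ties fall to the family with fewer parameters, then lower RMSE.

### Composite models

For a phase `p` and covariate subset `C` the composite model is a
binomial-logit GLM over accumulated doses,

    Pr(phase reached by day d) = logit⁻¹( β₀ + Σ_{c∈C} β_c Z_c(d) ),

fitted on daily rows: per environment one row per day offset
`d = 0 … 2·duration − 1`, labelled 0 before the observed end and 1 from
it onward — the equal-length post-end buffer balances the classes and
bounds the design size.  The model is purely additive; interactions are
out of scope by design.  Complete separation (possible on noise-free
synthetic data) falls back to a lightly ridge-penalized fit
(λ = 1e-6 on slopes); the unpenalized ML fit is always attempted first.

The decision threshold τ on the fitted probability is the Youden-optimal
ROC point (maximal sensitivity + specificity − 1) over midpoints of
consecutive sorted unique probabilities, computed with cumulative counts
in O(n log n); ties take the smallest τ.  Prediction walks the daily
probability forward from the phase start and returns the first day
`p ≥ τ`; a phase that never crosses within the horizon is explicitly
censored (never imputed), and censoring propagates through the chained
four-phase prediction.

All `2^k − 1` covariate subsets are enumerated in deterministic
(size, lexicographic) order — 127 per phase for the full seven
covariates, 508 over four phases.

### Model selection

* **Max_GT** — per complexity level (subset size), the model with the
  smallest duration RMSE on the held-out validation environments;
  overall winner is the global minimum.  Minimizes phenology-model
  uncertainty.
* **Max_CS** — only the Max_GT per-complexity winners are evaluated.
  Over a reference period where observed weather and scenario
  simulations coexist, each model predicts phase durations from a
  *fixed* start day-of-year (the median observed start; start DOYs ≥ 182
  are taken in the calendar year preceding the harvest year) under the
  observations and under every simulation.  Pooled per-simulation RMSEs
  are averaged within each RCM and then across RCMs, so over-represented
  RCMs carry no extra weight.  Minimizes climate-scenario uncertainty.
* **Opt** — per complexity, the mean of the two RMSEs; the winner is the
  smallest mean *within the closed complexity interval spanned by the
  Max_GT and Max_CS winners* (asserted on every run).

Every tie resolves toward fewer covariates, then the lexicographically
smaller subset id; all three strategies are pure functions of their
inputs.  Alternative readings of the scenario comparison are exposed as
switches on `select_max_cs` — uniform averaging over simulations
instead of RCM grouping, per-station RMSEs averaged afterwards instead
of pooling station×years, and averaging the simulated durations across
the ensemble before a single comparison — with the defaults as
described.

Skill scores in days can be standardized by the standard deviation of
the observed phase duration (`relative_uncertainty`) for comparison
across phases.

### Uncertainty propagation

Per covariate, observation-vs-simulation discrepancy over the reference
window is an RMSE on the min/max-standardized scale (pooled minimum → 0,
pooled maximum → 1, pooling observations and all simulations), matched
station-by-station and calendar-day-by-day, averaged uniformly over
simulations (the propagation step, unlike Max_CS, does not group by
RCM by default; a switch is provided).  For a covariate subset the
propagated error is the root sum of squares
`ε_f = √(Σ ε_i²)`, which assumes uncorrelated, roughly homoscedastic
errors — asserted as an assumption, not enforced.  ε_f is monotone in
the subset: adding a covariate can never reduce it.  Being on the
standardized scale it is unit-free and is never mixed with day-unit
RMSEs except through the explicit SD standardization above.

### Projection

Selected four-phase chains are applied to scenario ensembles from a
fixed sowing month-day (default October 30; autumn sowing belongs to
the calendar year preceding the harvest year).  Summaries: per-station
medians of phase dates (as days after emergence) within named 30-year
periods, with censored seasons excluded and their fraction reported;
and a two-sided ~30-season centered rolling mean per simulation and
station, followed by min/median/max envelopes across stations.  Near
the series ends the rolling window truncates symmetrically with a
minimum half-window of 5 seasons.  Seasons are labelled by harvest
year.

## Derived covariates

* **VPD** (hPa): Magnus saturation pressure
  `e_s(T) = 6.1078·exp(17.27·T/(T + 237.3))` times `(1 − RH/100)`;
  zero at saturation, monotone in both arguments.
* **SPI** (unitless): trailing 30-day precipitation sums; per calendar
  month (pooled across years) a gamma distribution is fitted by maximum
  likelihood to the nonzero sums with the zero fraction `q` as a point
  mass, `F(x) = q + (1 − q)·G(x)`; the probit transform `Φ⁻¹(F)` gives
  SPI.  At least five years of data are required; a month whose sums
  are all zero or constant is a degenerate-distribution error.  Whether
  the reference implementation pools by calendar month or fits the full
  record is not determinable; the per-month choice is standard for SPI
  and is not claimed to match any archive numerically.
* Gap handling: inputs must be gap-free; a linear interpolation utility
  covers gaps of at most 3 days, longer gaps are an error.

## The synthetic generator

Real phenology archives and scenario ensembles are not packaged; the
generator emulates their statistical structure so that every component
is testable against a known truth.

* **Weather**: per station, mean temperature is an annual sinusoid
  (default mean 9 °C, amplitude 9 °C, peak day 200) plus AR(1) anomalies
  (φ = 0.7, innovation SD scaled to a stationary 2 °C); tasmin/tasmax
  derive from positive spreads so the ordering invariant holds by
  construction; relative humidity is clipped to [20, 100]; rain is
  zero-inflated gamma (wet probability 0.5, shape 0.8, scale 5 mm);
  radiation is seasonal and non-negative.  Stations differ by a random
  mean offset (SD 0.8 °C).
* **Phenology**: from a fixed October 30 sowing, each phase ends on the
  first day its true β-weighted accumulated dose reaches the true
  required dose, plus rounded Gaussian observation noise (default SD
  2 days).  The default truth drives every phase with a Wang–Engel
  response to mean temperature with cardinals (0, 25, 35) °C — plausible
  wheat values used as test constants, not field estimates — and
  required doses (1.5, 6, 23, 32) chosen once so the default climatology
  yields emergence in ~1–5 weeks, jointing in April, heading in early
  June and senescence in late July.  A three-covariate variant drives
  the spring phase by temperature (weight 0.5), radiation (0.3) and
  humidity (0.2).
* **Scenario ensembles**: each simulation equals the observed weather
  plus per-covariate additive bias and AR(1) noise, extended beyond the
  observed years by recycling the seasonal structure (month-day lookup,
  Feb 29 borrowing Feb 28) and, optionally, a linear warming trend on
  the temperatures.  The trend and noise are applied to `tas` with the
  observed daily spreads re-attached, so tasmin ≤ tas ≤ tasmax survives
  perturbation.  RCM/GCM labels cycle through configurable lists.

What the generator does **not** emulate: spatial correlation between
stations, weather persistence beyond AR(1), realistic cross-covariate
dependence (beyond the temperature spreads), or the bias structure of
any particular scenario product.  Passing tests therefore demonstrate
the machinery's correctness and the selection logic's behaviour under
controlled uncertainty — not skill on any real archive.

## Validation experiments and problem sizes

The seeded experiments in `phenoselect.experiments` (run by the test
suite and by `scripts/acceptance.py`):

* **Cardinal recovery** — 20 replicates of ~500 environments
  (25 stations × 20 harvest years, 2-day duration noise) under a
  warm-summer climatology (tas mean 10 °C, amplitude 11 °C, anomaly SD
  3 °C).  A response parameter is only identifiable where the covariate
  visits it, so the optimum (25 °C) is assessed on the summer phase and
  the base (0 °C) on the spring phase.  Median absolute errors are
  typically well under 1 °C.
* **End-to-end selection** — one 120-environment bundle with the
  three-covariate truth: full family calibration per covariate
  (5-member ensembles to keep the run short; the 20-member default is
  exercised separately), subset-grid fitting, ground-truth selection.
  The winner's validation RMSE sits near the 2-day noise floor.
* **Selection logic** — with simulations identical to observations the
  scenario RMSE is exactly zero at every complexity and the compromise
  selection reduces to the ground-truth winner; with independent
  per-covariate scenario noise (tas 1.5 °C, GR 200 J/cm², RH 8 %), the
  scenario-driven winner uses no more covariates than the ground-truth
  winner in ≥ 80 % of 20 replicates — more covariates accumulate more
  scenario error, fewer lose ground-truth fit.
* **Projection sanity** — 20 simulations, 2 stations, reference
  2000–2029 extended to 2090.  Without a trend, distant 30-year period
  medians agree within ±2 days; with +0.04 °C/year on temperature,
  heading comes earlier in 2061–2089 than in the reference in every
  simulation (median shift around −19 days).

## Known limitations

* The calibration objective (duration RMSE with a median required dose)
  is one defensible choice; a dose-variance objective is equally
  plausible and not implemented.
* The single-covariate calibration surface has a near-flat ridge in
  (Ψ_base, Ψ_opt, Ψ_max, r) when the data do not span the cardinal
  range; the reported recovery results are conditional on climatologies
  that do.
* Frost/damage responses, covariate interactions, spatial interpolation
  and bias adjustment of scenario data are out of scope.
* The logistic fit treats daily rows within an environment as
  independent, which overstates the effective sample size; this affects
  standard errors (unused) but not the point estimates the pipeline
  consumes.
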