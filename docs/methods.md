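# Methods

## Problem and model

`scmort` estimates the effect of a one-time, single-unit policy change on an
annual mortality rate observed for ~50 comparable units (US states in the
motivating application).  The treated unit's counterfactual is a synthetic
control: a convex combination of donor units chosen to reproduce the treated
unit's pre-intervention outcome history.  Identification rests on the usual
synthetic-control assumptions: no interference between units, no
anticipation before the intervention year, and a latent-factor outcome
structure under which a good pre-period match implies a good counterfactual
post-period.  Nothing stronger than that is assumed — in particular no
parallel-trends restriction, which is why the interrupted time-series check
is a complement rather than a difference-in-differences.

## Pipeline stages and defaults

**Panels** (`panel.py`).  Long format (one row per unit-year) is canonical,
matching vital-statistics exports; rates are deaths per 100,000 and carried
at full read precision, with rounding applied only at display time (effects
2 d.p., deaths whole persons, percentages whole points).  Suppression
sentinels ("Unreliable", "Suppressed", empty) become missing cells.  There
is no imputation anywhere: a unit with a missing cell inside an analysis
window is simply ineligible for that window, which mirrors how small-count
suppression is handled in practice (drop the state, not the year).

**Study window** (`config.py`).  Defaults: pre-intervention 1999–2004,
intervention year T₀ = 2005, post window through 2019.  Re-dating to 2006 or
2007 lengthens the pre window to 7 or 8 years and scales the donor
similarity floor proportionately (⌈4/6 × pre-length⌉ = 5 and 6) so the
eligibility rule keeps the same stringency per year of data.

**Donor selection** (`donors.py`).  A donor-year is "close" when
|donor − treated| ≤ r with r = 2.0 × the treated unit's pre-period standard
deviation.  The band is deliberately scale-free: what counts as "similar"
for a series hovering near 9/100k differs from one near 20/100k, and tying
r to the treated unit's own variability makes the rule transferable across
demographic strata without re-tuning.  Eligibility requires closeness in at
least `min_similar_years` (default 4) of the pre years; up to 9 units most
often close from below and 9 from above are kept, ranked by close-year
count with mean |gap| breaking ties and unit id breaking remaining ties
(determinism).  A donor close from both sides in different years is assigned
its majority side, exact ties going to "below".  When fewer candidates
qualify the quotas shrink with a logged warning; zero qualifiers is an
error.

**Predictors and weights** (`scm.py`).  The predictor vector is the outcome
in every pre year plus the pre-period mean (7 predictors for a 6-year
window), with equal importance weights V.  A two-predictor variant (final
pre-year lag + pre mean) is available via `predictor_mode="lag_plus_mean"`;
the all-pre-years form is the default because with lagged-outcome-only
models the full history is what disciplines the weights, and nested
optimisation of V adds nothing when every predictor is the outcome itself.
Predictors enter on their raw scale (all share units).  The simplex-
constrained least squares is solved by SLSQP with an analytic gradient from
the uniform start (ftol 1e−14), followed by two safeguards: a necessary-
condition check that no single-donor vertex beats the solution (restarting
from the best vertex if one does), and a min-norm polish that, among weight
vectors with numerically equal objectives, returns the smallest-norm one so
collinear donors split weight reproducibly.  Weights are clipped at −1e−9
and renormalised to sum exactly to one.

**Inference** (`placebo.py`).  Each donor is refit as a pseudo-treated unit
against the remaining donors.  The per-year pseudo p-value uses the
+1/+1 finite-sample correction, p = (1 + exceedances)/(1 + N), so p = 0 is
unattainable from a finite permutation set and boundary stars are
reproducible; the test is two-sided on |gap| by default (the magnitude
comparison), with a one-sided option.  Attainable p-values lie on the grid
k/(N+1) — with fewer than 9 placebos no year can reach the 0.10 tier, which
is a property of the design, not a bug.  A pre-fit RMSPE filter (exclude
placebos fitting worse than 5 × the treated RMSPE) is available but off by
default.  The post/pre RMSPE-ratio statistic is a supplementary diagnostic,
not the primary test.

**Bias correction** (`robustness.py`).  For each post year, donor outcomes
are regressed by OLS (with intercept) on donor predictor vectors, and both
the treated unit's and the synthetic control's outcomes are residualised
against the fitted outcome model before differencing.  The regression is
per-year (the outcome model may drift across years) and unregularised —
with a single conceptual predictor there is nothing for shrinkage to do.
The pre-period-mean column is an exact linear combination of the pre-year
columns and is always dropped from the regression design; any residual rank
deficiency falls back to the minimum-norm least-squares solution.  When the
synthetic control matches the treated predictors exactly, corrected and raw
gaps coincide (verified in tests).

**ITSA** (`itsa.py`).  The treated unit is contrasted with the unweighted
donor-pool mean (population weighting optional) in one two-group segmented
regression: intercept, time centred at T₀, post indicator, post × elapsed
years, group, and all group interactions; the group × post-trend
coefficient is the headline difference-in-slopes.  No lagged dependent
variable enters the regression — adding one would change the estimand from
a trend break to a conditional-on-last-year contrast.  Errors are AR(1)
within each group's series, estimated by iterated Prais–Winsten implemented
in-module: the AR transform must be applied per group in the stacked
design, and the first observation of each series is retained with the
√(1−ρ²) scaling (so fixing ρ = 0 reproduces OLS exactly, a property the
tests exploit).  Exactly-fitting data yields zero residuals, in which case
ρ is set to 0 rather than left 0/0.  OLS with Newey–West (HAC, 2 lags)
standard errors is the alternative.

**Impact** (`report.py`).  A rate effect α on population P converts to
−α·P/100,000 avoided deaths; percent reduction is 100 × (synthetic −
actual)/synthetic.  The cumulative count defaults to the window from the
first year reaching the loosest significance tier through the last year,
and requires explicit per-year populations — no single-year population is
silently extrapolated.

## The synthetic panel generator

`simulate.py` draws panels with the structure the analysis assumes:
per-unit baseline + shared linear national trend + stationary AR(1)
Gaussian noise, plus an additive effect path on the treated unit.  Defaults:
20 units (1 treated + 19 donors), years 1999–2019, treated baseline 9.0
deaths/100k with donor baselines uniform on [8, 14] (a low-rate treated
unit near the bottom of the distribution), trend +0.15/yr (≈ +30% over the
panel), AR(1) ρ = 0.6 with innovation SD 0.3, treated population 39.5M with
donors at 6M (a mid-sized state; populations only scale the avoided-deaths
arithmetic), and an effect path that is zero for 2005–2009 then ramps
linearly to −2.2 deaths/100k at 2019 — a delayed-onset pattern consistent
with an intervention whose funding accumulates.  Negative rates are clipped
at zero (logged).  Output is bit-identical given the spec, and a null panel
shares every draw with its planted twin.

What the generator does *not* emulate: age-standardisation artefacts,
cross-state noise correlation, population drift, suppression-induced
missingness patterns, or any single-year anomalies.  Passing tests
therefore show that the machinery is correct and calibrated under the
stated statistical structure, not that real vital-statistics extracts
satisfy that structure.  Demographic strata are modelled by re-running the
generator with different baselines and effect paths, matching how each
stratum is analysed independently with its own donor pool.

## Replicated studies and problem sizes

`studies.py` packages the simulation studies the test suite and
`scripts/acceptance.py` run.  Sizes: 100 replicate panels for planted-ramp
recovery, 200 null panels for p-value calibration, 100 offset-donor
simulations for the bias-correction contrast, 20 replicate panels × 3
intervention dates for re-dating stability, 50 random 3-donor instances for
the optimizer-oracle comparison — enough replication that the Monte-Carlo
standard errors are small against each check's tolerance while the full
suite runs in minutes on one core.

One design choice deserves emphasis.  At the generator's default
donor-baseline spread the closeness rule selects very small pools (0–4
donors): most donors drawn from [8, 14] are simply not similar to a treated
unit at 9.0, which is realistic — and it means pool-filtered placebo
inference cannot reach p ≤ 0.10 at all (the grid floor 1/(N+1) exceeds it).
The estimator studies therefore run SCM, placebos and re-dating on the full
19-donor candidate set, where the exchangeability argument that defines the
placebo null distribution applies to the unit set actually permuted; the
selection rule itself is validated against brute-force oracles on fixtures
constructed to exercise it (including full 9+9 pools).  Re-dating stability
is likewise summarised as 20-replicate means of cumulative avoided deaths
over the common 2007–2019 window, since per-scenario significance gating
would compare sums over different year sets.

## Numerical choices and degenerate inputs

- Weight non-negativity tolerance 1e−9 (clip + renormalise); objective
  convergence ftol 1e−14; min-norm polish slack max(1e−12, 1e−9 × f*).
- The grid-search oracle comparison is two-sided but asymmetric: the solver
  must be within 1e−6 above the lattice optimum, while the lattice may
  exceed the continuous optimum by at most the analytic resolution bound
  (max pairwise donor-column distance² × step²).
- Pre window < 2 years, duplicate unit-years, non-numeric rates, and empty
  restrictions are hard errors; individual placebo failures are flagged and
  excluded, never fatal; an all-constant panel fails the ITSA design check.
- AR(1) ρ estimates are clipped to (−0.99, 0.99); a residual sum of squares
  below 1e−12 short-circuits ρ to 0.

## Known limitations

- Covariate-rich synthetic controls, penalised/augmented variants, and
  conformal or block-permutation inference are out of scope; the bias
  correction is the only regression adjustment offered.
- The closeness radius multiplier (2.0) is a default, not an estimate; on
  panels whose treated unit has an atypically quiet pre-period the band can
  be narrow and the pool small.  The multiplier is configurable.
- Pseudo p-values inherit the granularity of the placebo count; with small
  pools only coarse significance statements are possible.
- The generator's AR(1)-plus-trend world contains no confounding shocks
  that strike the treated unit alone post-intervention; on real data such
  shocks are indistinguishable from treatment effects, which is the
  method's fundamental caveat, not the implementation's.
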