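# Methods

## Design and estimand

The package estimates short-term (days-scale) associations between daily
mean temperature and daily counts of intentional self-harm (ISH) visits or
suicide deaths.  The design is a time-stratified case-crossover: every day
belongs to the stratum of days sharing its year, month and weekday, so each
case day is compared only with the 3–4 control days of its own stratum.
Conditioning on stratum totals removes all between-stratum variation —
long-term trends, seasonality at monthly resolution, and day-of-week
patterns — by construction.  What remains identifiable is the
*within-stratum* association between temperature history and counts.

The exposure–lag–response surface is a DLNM cross-basis: a natural cubic
spline in temperature tensored with a natural cubic spline in lag.  The
reported quantities are the cumulative relative risk over lags 0..L versus
the median temperature, the lag-specific RRs, the maximum-risk temperature
(MaxRT) within the 1st–99th exposure percentiles, and the P99-vs-P50
contrast used for subgroup comparison.

## Splines and the cross-basis

Natural cubic splines are implemented as the cardinal basis on the knot
sequence (boundary knots at the observed min/max, interior knots at
configurable percentiles): basis function *j* is the natural interpolating
spline through the *j*-th unit vector.  Natural boundary conditions make
the basis linear beyond the boundary knots; evaluation outside continues on
the boundary tangent, so prediction grids may extend past the fitted range
without cubic blow-up.  The exposure basis carries no intercept (absorbed
by the model); the lag basis carries one — the usual DLNM identifiability
convention.

Lag knots sit at `L^(i/(k+1))`, i.e. evenly spaced on the log-lag scale
with boundary knots 0 and L.  The lag-spline dimension is a free choice:
the default is one interior knot (the smallest nondegenerate layout for
L = 2), reused for the sensitivity lags 3 and 6.  For L = 1 the lag space
degrades to intercept + linear; for L = 0 the lag basis is the intercept
alone and the cross-basis reduces to the exposure basis.

Quantiles (knot placement, percentile contrasts, MaxRT search bounds) use
linear interpolation between order statistics, computed over **all days of
the study window**, not case days only.  The RR grid has 0.1 °C resolution
with the exact empirical 1st–99th percentile points appended, matching the
0.1 °C precision at which MaxRT is reported.

## Conditional quasi-Poisson fit

The conditional likelihood (stratum totals fixed) is multinomial within
strata; its maximizer equals the fixed-effects Poisson MLE.  Fitting
absorbs the strata instead of estimating dummy intercepts: each IRLS
(= Newton, canonical link) step profiles the stratum intercepts in closed
form and performs weighted within-stratum centering, giving O(strata)
memory.  The dense-dummy GLM route is retained in the tests as an oracle
and agrees to 1e-8 in coefficients and covariance.

Numerical choices: iteration stops when the relative deviance change is
below 1e-9 **and** the score norm is below 1e-6 (cap 50 iterations; the
score condition typically costs one extra quadratically-convergent step).
Days without a full lag history and strata with zero events are excluded
from the likelihood (all-zero strata contribute constants).  Collinear
columns are detected by QR on the centered design and reported by name.

Overdispersion is estimated as Pearson χ² over residual degrees of freedom
`n − k − S` (slope parameters plus absorbed stratum intercepts), and scales
the covariance: `vcov = φ̂ · I⁻¹`.  Confidence intervals are Wald on the
log scale with the normal 0.975 quantile (1.96).

QAIC defaults to `−2ℓ/φ̂ + 2k` with ℓ the conditional log-likelihood
(multinomial coefficient dropped — constant across candidate bases) and
*k* the slope-parameter count; the alternative convention
`−2ℓ + 2φ̂k` is available via a flag since the literature uses both.
Knot selection fits each candidate percentile set and returns the QAIC
minimizer, breaking ties toward fewer knots, then list order.

The dewpoint covariate enters as a same-day 3-df natural cubic spline
(interior knots at the 33rd/67th dewpoint percentiles, boundary at
min/max); the holiday indicator has a single shared coefficient.

## Synthetic data: what it emulates and what it does not

`WeatherParams` defaults target the Seoul climate scale: annual mean
13.4 °C, cosine annual cycle of amplitude 14 °C completing exactly
`n_years` cycles over the series (so whole-series means are exact), AR(1)
day-to-day noise with stationary SD 3 °C and autocorrelation 0.6, a 9 °C
diurnal range for min/max, and dewpoint = mean − 8.7 °C plus independent
noise (SD 5 °C).  These reproduce a ~13.4 ± 10.5 °C mean-temperature
distribution.

`RiskSurface` fixes the ground truth behind simulated counts: a lag-0
log-RR function spread over lags by non-negative weights summing to 1, a
baseline rate (default 16.2 events/day, the scale of a large-city ISH
series; deaths are sparser), day-of-week offsets, a seasonal log-rate
modulation, a holiday offset, and an overdispersion factor (default 1.5 —
a free choice, as empirical dispersion in such registries is rarely
published) realized as a gamma-Poisson mixture with variance `φμ`, i.e.
a negative binomial with matched moments, chosen for closed-form moment
checks.  Case records then dress the daily counts with registry schema
fields (sex/age cell, mechanism, intentionality, ER and
post-hospitalization outcomes); ER deaths spawn a parallel death-registry
row whose ICD-10 code in X60–X84 matches the mechanism.

What the generator does **not** emulate: spatial exposure heterogeneity,
measurement error from single-station monitoring, air-pollution
confounding, registry coverage drift, and within-person dependence of
repeat visits.  Passing tests therefore demonstrate correctness of the
estimator under its own assumptions, not robustness to those real-data
features.

### Calibration experiments and the seasonal term

The calibration studies (slope recovery, CI coverage, type-I error,
lag-choice robustness) simulate with day-of-week, holiday and
overdispersion effects switched **on** — strata absorb the first exactly
and the model estimates the second — but with the seasonal log-rate
modulation set to zero.  A smooth seasonal trend aligned with temperature
is *within-month* confounding: month strata only remove monthly means, so
no estimator of this design could be unbiased under it.  Keeping it out of
the calibration conditions separates estimator error (what the tests
measure) from design-level residual confounding (a known property of
time-stratified referents, flagged here as a limitation).  The generator's
default `season_amplitude = 0.10` remains available for experiments on
exactly that sensitivity.

Problem sizes: calibration uses 200 replicates of ~2,000-day series (six
simulated years, truncated), which puts Monte-Carlo error comfortably below
the effect sizes probed; the lag-robustness comparison uses 25 replicates
per maximum lag.

## Known limitations

- With the true lag response concentrated at lag 0, a long lag window
  (L = 6) with the default 3-dimensional lag spline cannot represent the
  spike exactly; the cumulative log-RR then shows a small projection
  attenuation (of order 0.03 on the log scale in the calibration setup) —
  well inside single-estimate uncertainty, which is the sense in which the
  lag-choice sensitivity is "robust", but visible when averaging many
  replicates.
- The Pearson-χ²/df dispersion can be noisy in sparse subgroups (few events
  per stratum); intervals there inherit that noise.
- MaxRT is reported at grid resolution (0.1 °C) and, for monotone curves,
  coincides with the P99 search bound by construction.
- Percentile-contrast interpolation is linear in the contrast vectors
  between grid points; with the exact percentile points appended to the
  grid this matters only for off-grid queries.
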