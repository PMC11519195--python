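# heatlag

Short-term associations between ambient temperature and intentional
self-harm (ISH) or suicide deaths, estimated with a **distributed lag
nonlinear model (DLNM)** under a **time-stratified case-crossover design**
and **conditional quasi-Poisson regression**.

The package is aimed at environmental-epidemiology analysts working with
daily event counts (emergency-department self-harm visits, cause-of-death
records coded ICD-10 X60–X84) and single-station weather series.  Because
such registries are typically restricted-access, `heatlag` ships a
first-class synthetic-data module that generates weather, daily counts and
individual-level case records from a *known* exposure–lag–response surface,
so every stage of the pipeline can be validated against ground truth.

## Model

Daily counts are modelled as

```
Y_t ~ quasi-Poisson(μ_t)
log(μ_t) = α + β·T_{t,ℓ} + S(DT_t, 3) + λ·Stratum_t + η·Holiday_t
```

where `T_{t,ℓ}` is the DLNM **cross-basis** of mean temperature — the tensor
of a natural cubic spline in temperature (interior knot at the 50th
percentile for suicide deaths; 25th/50th/75th for ISH, choices comparable by
QAIC) with a natural cubic spline in lag (knots evenly spaced on a log
scale, maximum lag 2 days) — `S(DT_t, 3)` a 3-df natural cubic spline of
daily mean dewpoint temperature, and `Stratum_t` the (year, month, weekday)
cell of day *t*.  Conditioning on stratum totals eliminates the `λ` nuisance
intercepts (the fit is equivalent to conditional logistic regression on
matched sets, while also estimating a Pearson overdispersion `φ̂` that
scales the covariance).

From a fit the package derives the cumulative and lag-specific relative-risk
curves versus the median temperature with delta-method Wald CIs, the
**maximum risk temperature (MaxRT)** inside the 1st–99th exposure
percentiles, and the **RR at the 99th vs the 50th percentile** used for
subgroup comparison (sex × age bands 0–34 / 35–64 / ≥65).  A sensitivity
suite swaps the maximum lag (2/3/6 days) and the exposure series
(mean/min/max temperature).

## Worked example

```python
import numpy as np
import heatlag as hl
from heatlag.cohort import Subgroup
from heatlag.pipeline import AnalysisConfig

weather = hl.simulate_weather(hl.WeatherParams(seed=11))
ref = float(np.percentile(weather["tmean"], 50))
surface = hl.RiskSurface(               # ground truth: log-RR = 0.02/°C at lag 0
    exposure_fn=hl.linear_exposure(0.02, ref), reference=ref, season_amplitude=0.0
)
records, deaths = hl.simulate_case_records(weather, surface, seed=12)

config = AnalysisConfig(
    outcomes=("ish_nonfatal", "suicide_death"),
    subgroups=(Subgroup(), Subgroup(sex="female"), Subgroup(sex="male")),
    seed=11,
)
out = hl.run_analysis(config, weather, records, deaths, write=False)
print(out["summary"][["outcome", "sex", "n_events", "maxrt",
                      "rr_p99", "rr_p99_lo", "rr_p99_hi"]].round(3).to_string(index=False))
```

prints

```
      outcome    sex  n_events  maxrt  rr_p99  rr_p99_lo  rr_p99_hi
 ish_nonfatal    all     35038 31.172   1.477      1.306      1.670
 ish_nonfatal female     20940 31.172   1.499      1.293      1.738
 ish_nonfatal   male     14098 31.172   1.447      1.208      1.732
suicide_death    all      1374 31.172   2.249      1.291      3.916
suicide_death female       809 31.172   2.156      1.057      4.397
suicide_death   male       565 31.172   2.436      1.031      5.758
```

The generating surface implies a true RR(P99 vs P50) of
`exp(0.02 × (31.2 − 13.3)) = 1.428`; the all-group ISH estimate (1.48,
95% CI 1.31–1.67) covers it, the effect is monotone so MaxRT lands at the
99th-percentile search bound, and the sparse suicide-death series shows the
same effect with appropriately wider intervals.

The same study runs from the shell:

```sh
heatlag simulate --out data --seed 11
heatlag run-all --config config.yaml     # paths + outcomes + subgroups in YAML
heatlag sensitivity --config config.yaml
```

## Layout

- `heatlag.synthetic` — weather, daily-count and case-record generators
- `heatlag.cohort` — inclusion/exclusion filters, subgroups, daily aggregation, descriptive tables
- `heatlag.strata` — time-stratified (year, month, weekday) referent scheme
- `heatlag.basis` — natural cubic splines, percentile/log-lag knots, cross-basis
- `heatlag.model` — conditional quasi-Poisson fit, dispersion, QAIC, knot selection
- `heatlag.effects` — RR curves, delta-method CIs, MaxRT, percentile contrasts
- `heatlag.pipeline` / `heatlag.cli` — full-study orchestration and the `heatlag` command
- `docs/methods.md` — modelling assumptions, defaults and limitations
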