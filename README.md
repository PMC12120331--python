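# hrtag

Biologging heart-rate analysis for archival tag deployments on large
fish — quality control and daily aggregation of heart-rate tag records,
and Bayesian selection among nested identity-link Poisson regression
models with a temperature change-point, for studying how temperature
and feeding drive the daily median heart rate of a captive Atlantic
bluefin tuna (*Thunnus thynnus*).

Heart-rate tags implanted near the heart log, every 10 minutes, an
ECG-derived heart rate with a quality index (QI, 0 = excellent to
3 = poor), peripheral temperature, and an external-acceleration
activity metric (AvgEA, milli-g). Over a multi-month deployment the
interesting physiology lives at the daily scale: the post-feeding rise
in metabolic rate (specific dynamic action) shows up as a feeding
effect on daily median heart rate — but only below a threshold
temperature, above which the effect disappears. `hrtag` implements the
full chain from raw records to that threshold estimate, plus a
synthetic-data generator that emulates a whole deployment so every
stage is testable without access to tag data.

## The model

Daily median heart rate `HRm_t` (integer bpm) is modelled as

```
HRm_t ~ Poisson(mu_t)
mu_t  = alpha + sum_i beta_i * X_{i,t}
```

with an **identity** link — `mu` is linear in the covariates, with
positivity enforced during sampling — over daily covariates: total feed
TF (tons), median peripheral temperature TPm (°C), temperature
interquartile range TPiq (°C), and median activity ACm (milli-g). One
coefficient may switch at an estimated change-point in a governing
covariate:

```
beta_TX = beta_plus   if TX_t > thresh
          beta_minus  if TX_t <= thresh
```

All 21 covariate subsets with at most one threshold form the nested
family (`hrtag.enumerate_models()`). Each member is fitted by
componentwise random-walk Metropolis (3 chains × 10,000 kept draws
after 10,000 burn-in, adaptation frozen at burn-in's end; vague
Normal(0, 100) priors on coefficients, uniform prior on the threshold
over the governing covariate's central range). Models are compared by
DIC (`DIC = Dbar + pD`), R², and checked for convergence with the
classical Gelman–Rubin R-hat.

## Worked example

Fit the change-point model to a simulated 80-day deployment
(`python examples/04_fit_change_point_model.py`):

```
model: alpha + TF:thresh + TPm  (80 days)
                 mean     sd    q2.5   q97.5   rhat
parameter
alpha          50.208  0.850  48.530  51.932  1.001
beta_plus_TF    0.372  0.608  -0.842   1.469  1.000
beta_minus_TF   1.712  0.217   1.289   2.140  1.003
beta_TPm        1.787  0.332   1.129   2.451  1.000
thresh         24.900  1.063  21.583  26.146  1.000
DIC = 539.2  pD = 4.69  R2 = 0.601  max R-hat = 1.003
```

Reading the output: at average conditions the fish beats ~50 times a
minute (`alpha`). Below the estimated ~25 °C threshold each ton of feed
raises daily median heart rate by ~1.7 bpm (`beta_minus_TF`, the
specific-dynamic-action signal); above it the feeding effect's credible
interval spans zero (`beta_plus_TF`). Each °C of daily median
temperature adds ~1.8 bpm (`beta_TPm`). R-hat ≈ 1 says the three chains
agree. The generating truth (alpha 50.188, beta_plus 0.313, beta_minus
1.831, beta_TP 2.137, thresh 25.462) sits inside the intervals.

The other `examples/` scripts cover simulation, ECG → bpm, QC +
aggregation, DIC ranking, and the one-call pipeline. The same pipeline
is available from the shell:

```
hrtag run-all --seed 5 --outdir run/
```

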