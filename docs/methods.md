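# Methods

## Observation model

Daily median heart rate `HRm_t` is a non-negative integer (the tag
reports integer bpm, and daily medians are rounded half-up before
fitting), so it is modelled as Poisson with an **identity-link** linear
mean:

    HRm_t ~ Poisson(mu_t),    mu_t = alpha + sum_i beta_i (X_{i,t} - c_i)

The identity link keeps every parameter in natural, physiologically
readable units: `alpha` in bpm, feeding slopes in bpm/ton, temperature
slopes in bpm/°C. Its price is a positivity constraint — `mu_t > 0` is
not guaranteed by the link — which the sampler enforces by rejecting
any proposal that makes some `mu_t` non-positive (equivalently, the
prior is truncated to the feasible region).

Covariates are mean-centered before fitting (`c_i` = column mean), so
`alpha` is the expected heart rate at average conditions; slopes are
unaffected by centering. The change-point is compared against the
**uncentered** governing covariate, so the threshold is reported in
natural units (°C). Equality at the threshold takes the "below" branch
(the defining inequalities are strict on both sides, leaving equality
to convention).

A coefficient may switch at the change-point:

    beta_M(t) = beta_plus  if G_t > thresh,  else beta_minus

The model family is every ordered subset of {TF, TPm, TPiq, ACm} with
at most one switched coefficient — 21 structures. In the structure
labels, a temperature variable (`TPm`, `TPiq`) self-thresholds (its own
slope switches at a value of itself); for any other variable
("TF:thresh", "ACm:thresh") the slope switches at a threshold in TPm,
temperature being the physiological gate. This also covers structures
such as `alpha + TF:thresh`, where TPm governs the switch without
itself entering the mean: the governing variable is a data column, not
necessarily a regressor. Governance is configurable per `ModelSpec`.

## Priors

Coefficients (intercept and slopes) get Normal(0, sd 100) — effectively
flat over the plausible range (heart rates live in 8–120 bpm). The
threshold gets a uniform prior over [q10, q90] of the governing
covariate, further clipped so at least 3 observations fall strictly
above and at-or-below every admissible value; without that clip the
threshold can escape to a region where one regime is empty and the
switched slopes lose identifiability.

## Sampler

Componentwise Gaussian random-walk Metropolis. During burn-in only,
each component's step size adapts by Robbins–Monro
(`scale *= exp((rate - 0.44)/sqrt(batch))`, batches of 50) toward the
0.44 acceptance rate that is optimal for one-dimensional updates; the
scales are frozen before any draw is retained, so the retained chains
come from a fixed Markov kernel. Chains start from overdispersed
perturbations of a least-squares (method-of-moments) estimate, with the
threshold drawn uniformly over its prior support; infeasible starts are
contracted toward the moment estimate, with the intercept-at-mean point
(always feasible) as a last resort. Default protocol: 3 chains, 10,000
burn-in, 10,000 retained draws per chain. A chain that accepts no move
for some component after burn-in raises a sampler error rather than
returning silently frozen draws.

## Model comparison and diagnostics

* `DIC = Dbar + pD`, with `Dbar` the mean of `D = -2 log L` over pooled
  retained draws and `pD = Dbar - D(theta_bar)` at the pooled posterior
  mean. A five-point DIC gap is treated as a real improvement, and ties
  are broken toward fewer parameters. `pD` can come out negative when
  the posterior mean is a poor plug-in (typical of a multimodal
  threshold posterior on short chains); it is reported as-is with a
  warning rather than clamped.
* `R² = 1 - SSE/SST` at posterior-mean predictions. It may be negative
  (a model predicting worse than the response mean), which is why the
  intercept-only model can score slightly below zero.
* Convergence: classical (non-split) Gelman–Rubin potential scale
  reduction from between/within-chain variances, threshold 1.1. On
  literally duplicated chains the estimator returns
  `sqrt((n-1)/n)` ≈ 1, as the formula dictates.

## Quality control and aggregation

Records with QI ∈ {2, 3} are dropped, as are heart rates strictly above
120 bpm or strictly below 8 bpm. The bounds themselves survive: 8 bpm
is the lowest rate measurable in the tag's ECG window (one full
inter-beat interval must fit, 60 / 7.5 s = 8 bpm), so it must be
admissible. Drop reporting uses first-rule-wins precedence (QI, then
high HR, then low HR); precedence affects tallies only, never
membership. Daily summaries use medians (HRm rounded half-up to keep
the Poisson support), a linear-interpolation (type-7) quantile
convention for TPiq (configurable), and drop days with no surviving
records rather than imputing them.

## Synthetic deployment generator

The generator emulates the deployment the analysis was designed for;
its defaults are the study conditions, not tuning knobs:

* 80 days × 144 records/day (10-minute cadence; real deployments have
  gaps, available as `dropout_prob`, default 0).
* TPm declining linearly 27.5 → 19 °C with 0.4 °C daily noise; TPiq
  rising 0.3 → 1.2 °C (day-to-day lognormal spread); ACm drifting
  30 → 40 mg with noise.
* Daily feed: right-skewed Beta(2,3) on [0, 20] t, with fasting spells
  (TF = 0) starting at 6%/day and geometric mean length 2.5 days —
  producing the multi-day fasts seen in farm feeding logs.
* Daily true HRm drawn Poisson from the change-point model with the
  reference posterior means (alpha 50.188, beta_plus 0.313, beta_minus
  1.831, beta_TP 2.137, thresh 25.462 °C) as generating truth. Under
  these conditions the pooled valid heart rates have median ≈ 50 bpm.
* Within a day, heart rates scatter around the true level with integer
  discretized-normal jitter (sd 6 bpm). The jitter is quantile-balanced
  (stratified normal quantiles, shuffled) separately for the records
  that will survive QC and the rest, and each group is re-centered so
  its median rounds to zero; since the median of a union of multisets
  lies between the subset medians, both the raw and the post-QC daily
  median round back to the true HRm essentially always. Corrupted
  records get out-of-bounds heart rates with balanced low/high sides
  for the same reason.
* QI is 0/1 with probability `1 - qi_bad_prob` (default 0.15, leaving
  ~85% of records usable), else 2/3; 30% of bad-QI records also get a
  wild out-of-range heart rate, and an independent `hr_oob_prob`
  (default 0) can spoil any record, so the expected pass rate is
  `(1 - qi_bad_prob) * (1 - hr_oob_prob)`.
* ECG bursts are Gaussian-bump PQRST composites — only R-peak timing
  matters downstream; acceleration bursts put the tail-beat oscillation
  along the gravity axis so it modulates the vector norm that the EA
  metric measures.

What the generator does **not** emulate: diel rhythms, behavioural
autocorrelation, cage hydrodynamics, the bimodal shape of the pooled
HR histogram beyond what the seasonal trend induces, or the tag's
proprietary QI algorithm (QI corruption is a coin flip, not a
signal-quality model). Passing tests therefore demonstrate that the
pipeline and estimator work under the model's own assumptions plus
realistic record-level noise — not that the model is correct for any
particular animal.

## Signal metrics

R-peak detection is a thin policy over `scipy.signal.find_peaks`:
local maxima above 0.6 × the trace maximum, separated by ≥ 0.45 s
(a ~133 bpm ceiling, just above the 120 bpm QC bound). Heart rate is
60 / mean(R-R), rounded half-up to integer bpm like the tag's output.
The external-acceleration metric is `| ||a|| - g |` per sample
(milli-g), averaged over the burst; the absolute value (rather than the
signed difference) guarantees the non-negativity its interpretation as
"activity" assumes, and a `signed` mode is available.

## Numerical and design notes

* Seeds: every stochastic component takes an explicit seed;
  deployment-level generators derive independent substreams per stage
  (`SeedSequence([seed, stage])`), and the pipeline fans a single seed
  out by fixed offsets so stages are independently reproducible.
  Identical config + seed gives byte-identical artifacts.
* All numeric text output uses 6 significant digits for diff-stability.
* Parameter-recovery study (the package's headline check): 10
  replicates of 80 days, full MCMC protocol, posterior means averaged
  over replicates. One full study takes ~1 minute on one CPU. The
  threshold's posterior mean carries a small (~0.3 °C) downward
  shrinkage from its asymmetric uniform support — well inside its
  posterior SD. The above-threshold feeding slope rests on only ~20
  days per replicate, so individual replicates can land a few posterior
  SDs from truth even though the replicate average is accurate.
* Demonstration scripts and most simulation tests use shortened chains
  (hundreds to a few thousand draws); these sizes are stated inline and
  chosen so Monte Carlo error stays well below the quantities being
  checked. Quadrature (dense-grid) posteriors serve as independent
  oracles for small models; statsmodels' identity-link Poisson GLM
  cross-checks the likelihood and point estimates.

## Known limitations

* No gamma observation model, no multiple thresholds, no time-series
  autocorrelation, no WAIC/LOO — DIC only, by design.
* The identity link means badly mis-specified starting points can be
  infeasible; the sampler handles this, but models whose posterior
  concentrates near the positivity boundary will mix slowly.
* Days are calendar days at midnight boundaries; no timezone or DST
  handling.
* The threshold prior's observation-count clip makes the prior (hence,
  weakly, the posterior) depend on the observed covariate range.
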