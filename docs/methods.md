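# Methods

## The estimation problem

A single well-preserved skull of the giant Miocene caiman *Purussaurus
brasiliensis* (specimen UFAC 1403) preserves one usable measurement: a
dorsal cranial length (DCL) of 1400 mm. Everything else of biological
interest — body length, body mass, bite force, food demand — must be
inferred. The inference rests on the strong allometric regularity of
crocodilian body proportions: across species and ontogeny, pairs of body
measures follow power laws `y = 10^a · x^b`, linear on log10–log10 axes.

The pipeline chains four bivariate regressions calibrated on extant
crocodilians:

| stage | predictor → response | units | intercept a | slope b |
|-------|----------------------|-------|-------------|---------|
| 1 | DCL → SVL (snout-vent length) | mm → cm | −0.56913 | 1.10776 |
| 2 | SVL → TTL (total length)      | cm → cm | 0.41689  | 0.91905 |
| 3 | TTL → BM (body mass)          | cm → kg | −5.1240  | 2.9221  |
| 4 | BM → BF (sustained bite force)| kg → N  | 2.21779  | 0.66776 |

Each stage feeds its point estimate to the next. The embedded coefficients
above (`crocallometry.chain.PUBLISHED_COEFFICIENTS`) define the package's
reference chain; `fit_chain` re-derives a chain of the same shape from any
pair of calibration tables.

The unit convention (DCL in mm, lengths in cm, mass in kg, force in N) is
locked by the reference reproduction: stage 1 yields the reference 824.2 cm
only when a 1400 mm skull enters in millimetres.

## Fitting

Each stage is ordinary least squares on log10-transformed data
(`LogLogRegression`, a scikit-learn-style estimator; closed-form normal
equations). OLS — rather than reduced major axis or another symmetric line
fit — is the right choice when the object is prediction of `y` from `x`.
Log transformation homogenises the variance and makes the power law linear.
The Pearson correlation `r` of the log pairs is the reported fit statistic.

Degenerate inputs are rejected rather than guessed at: fewer than 3 pairs,
any non-positive or non-finite measurement, or a constant predictor raise
errors naming the offending row/stage. A constant *response* is legal and
yields slope 0.

## Bootstrap uncertainty

Coefficient uncertainty uses a nonparametric case-resampling bootstrap:
pairs are resampled with replacement, the fit repeated per replicate
(default 1000 replicates), the standard error is the standard deviation of
the replicate coefficients, and the 95% confidence interval is the
percentile interval. Case resampling with percentile intervals makes no
assumption about the residual distribution and suits small morphometric
panels. Replicates whose resample has a constant predictor are redrawn (at
most 100 redraw rounds, then an error). The replicate coefficients are kept
on the fitted model (`boot_intercepts_`, `boot_slopes_`) for audit and for
the Monte-Carlo propagation mode.

A calibration caveat, measured with this package's own generator: at the
default panel sizes (23–30 rows) the true coverage of the 95% percentile
interval is about 0.91–0.92, the textbook small-sample undercoverage of
percentile bootstrap CIs (analytic t-based CIs cover at the nominal 0.95 on
identical panels; BCa intervals do not materially improve on percentile
here). Users who need calibrated small-sample coverage should prefer the
analytic intervals of a fitted model.

All randomness flows through `numpy.random.default_rng` with explicit
seeds; the package default seed is 20150217, and every report embeds the
seed and configuration it was produced with.

## Prediction limits

For a new individual at predictor `x0`, the 95% prediction interval on the
log10 scale is the classical OLS form

    a + b·log10(x0) ± t(0.975, n−2) · s · sqrt(1 + 1/n + (log10(x0) − m̄)² / Sxx)

back-transformed with `10^(·)`. Back-transformation makes every interval
multiplicatively symmetric about its point (`upper/point = point/lower`),
the structure the reference intervals display. A bootstrap-flavoured
alternative (`method="bootstrap"`: resampled fitted line plus a resampled
residual, symmetric quantile of the absolute log deviation) is available
behind the same contract. Models built from published coefficients carry no
fit diagnostics and explicitly refuse to produce prediction limits.

Per-stage limits in a chained estimate are evaluated at the stage's own
incoming point estimate, **not** compounded through the chain; the
reference intervals have exactly this per-regression structure (chaining a
stage's printed bounds does not reproduce the next stage's printed bounds).
Total chained uncertainty is therefore deliberately understated, and every
`ChainResult` says so in its `interval_note`. The optional `mc_propagate`
mode propagates coefficient draws and fresh residual noise through the full
chain for comparison; its limits widen downstream, as expected.

## Feeding ecology

Seasonal field constants for Nile crocodiles give
`log10(BM / daily intake) = 2.151` (growing season) and `2.592`
(non-growing season), so daily intake is `BM / 10^c` kg/day and `10^c` is
the number of days needed to consume one body mass. Intake is linear in BM
and the day counts are size-independent — a first-appraisal assumption when
extrapolated to a multi-tonne animal, adopted here without metabolic
correction.

Reporting arithmetic matters at the last digit: seasonal rates are quoted
at 1 decimal (half-up, computed in integer tenths so binary floats cannot
flip the rounding), the mean rate is the mean of the two quoted rates, and
day counts divide body mass by the quoted rates before rounding half-up to
whole days. For the reference body mass 8423.9 kg this yields 59.5 and 21.6
kg/day, mean 40.6 kg/day, and 142 / 390 days; full-precision values are kept
alongside on the `IntakeEstimate` (the full-precision mean is 40.53). If a
quoted rate would be 0.0 kg/day (body mass under ~15 kg), the day count
falls back to the full-precision rate.

## Synthetic calibration panels

`simulate_crocodilian_panel` emulates the *statistical structure* of the
real calibration data, not its values: a ~30-row single-species ontogenetic
series carrying (DCL, SVL, TTL) and a 23-row cross-species panel carrying
(TTL, BM, BF). Predictors are sampled log-uniformly (leverage spread evenly
on the fitted scale) over realistic ranges — skull lengths 20–700 mm, total
lengths 30–600 cm — so a 1400 mm skull is an extrapolation, as in the real
analysis. Responses are generated through the chain itself: each downstream
column applies the published stage coefficients to the realised upstream
column plus Normal(0, `noise_sd`) log10 scatter, so within-table
relationships carry known ground truth. Default `noise_sd` is 0.05; over
the full simulated size ranges this produces Pearson r near 0.99, at the
high end of the 0.94–0.98 reported for the real panels (whose narrower
effective ranges and measurement heterogeneity the generator does not
attempt to mimic).

What the generator does *not* emulate: mixed ontogenetic/interspecific
sampling, measurement error in the predictor, sexual dimorphism, or
phylogenetic structure. Passing tests therefore demonstrate correctness of
the estimation machinery under the assumed power-law-with-lognormal-noise
model, not robustness of the biology.

## Numerical and scale choices

- Log base 10 throughout; natural logs never surface in the API.
- Internal values at full double precision; rounding to presentation
  precision happens only in report rendering.
- CSV I/O writes `%.17g` and reads with round-trip float parsing, so
  write-then-read is bit-exact.
- Simulation-based test scales: coverage checks use 400–500 replicate
  panels and 1000 bootstrap replicates (the vectorised bootstrap makes the
  full replication count cheap); bias checks use 200 panels. These sizes
  give binomial standard errors of ~1 percentage point on coverage
  estimates.
- Per-stage bootstrap seeds in `fit_chain` are derived as
  `seed + 7919·stage` (mod 2³¹) so stages are independent but the chain is
  reproducible from one seed.

## Known limitations

- Every fossil estimate is an extrapolation far beyond the calibration
  range; prediction intervals quantify scatter about the fitted line, not
  the correctness of the power law outside it.
- Per-stage intervals understate total chained uncertainty (see above);
  `mc_propagate` bounds the effect but still conditions on the assumed
  model form at every stage.
- The feeding constants derive from one extant species and are applied far
  outside the mass range that produced them.
- Percentile bootstrap CIs under-cover slightly at panel sizes below ~50
  (measured ~0.91 at n=23); this is a property of the method, retained for
  fidelity to the standard workflow it mirrors.
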