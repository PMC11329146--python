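# Methods

## Model

License counts are annual administrative totals per province, nested in
regions. We model them as negative binomial in the (mean, dispersion)
parameterisation, `Var = mu + mu^2/theta` — the parameterisation in which a
single global `theta` expresses proportional extra-Poisson noise, which is
what year-to-year registry fluctuation looks like. The log mean combines

- a global intercept `alpha`,
- region effects `u_r` with a hard sum-to-zero constraint,
- province effects `v_p` constrained to sum to zero *within each region*
  (a global-only constraint would leave `u_r` confounded with the
  within-region mean of `v`; within-region zero sums imply the global zero
  sum as well),
- a linear year trend `beta (t - t0)`, `t0` the first training year, and
- a shared first-order random-walk year effect `gamma_t`, anchored at
  `gamma_{t0} = 0`, which absorbs common non-linear shocks (weather,
  regulation, fee changes) that a straight line cannot.

`theta` is global; per-region dispersion is out of scope. The random walk is
shared across provinces: the model deliberately attributes common-year
variation to `gamma` and leaves province-idiosyncratic variation to the NB
noise.

### Priors

Weakly informative and config-overridable (`PriorSpec`):

| parameter | prior | default rationale |
|---|---|---|
| `alpha` | Normal(log grand mean count, 1.5) | centres on the data scale; sd 1.5 spans a ~20x range |
| `beta` | Normal(0, 0.2) | ±20%/year trends are already extreme for licenses |
| `sigma_u`, `sigma_v` | half-Normal(1) | log-scale spread of regions/provinces |
| `sigma_gamma` | half-Normal(0.5) | common shocks of a few percent a year |
| `1/theta` | Exponential(rate 0.1) | near-flat over the inverse dispersion; admits near-Poisson (`theta` in the thousands) as well as strongly overdispersed panels |

The dispersion prior is deliberately placed on `1/theta`: administrative
counts can be near-Poisson, and a prior directly on `theta` with light tails
would cap the dispersion at odds with the narrow predictive intervals such
registries support.

### Inference

A self-contained adaptive Metropolis-within-Gibbs sampler (numba-compiled,
`huntwatch._sampler`). Single-site Gaussian random-walk proposals with
Robbins-Monro adaptation of each step size toward 44% acceptance during
warmup (frozen afterwards), plus three joint moves that are essential for
mixing:

- *level*: `alpha` up, `gamma` down (the likelihood is invariant except at
  the anchored first year);
- *slope*: `beta` up, the random-walk drift down (likelihood-invariant);
- *funnel*: rescale `gamma` and `sigma_gamma` together — the increment
  prior is invariant and the Jacobian cancels, which decouples the
  random-walk states from their scale (the classic funnel).

Internally time is centred at the training mean to decorrelate intercept
and slope; reported draws are converted back to the first-training-year
parameterisation. Defaults: 2 chains, 2000 warmup, 2500 retained draws per
chain (at 2x1000 a minority of fits left the `sigma_gamma` split-R-hat
marginally above 1.05; the default gives headroom at ~1.4 s per 50-province
fit). A fit with any split-R-hat above 1.05 is flagged unusable — pipeline
and selection refuse to use it silently.

Correctness of the sampler is checked against a dense grid-quadrature
posterior on the 2-parameter single-unit submodel (total variation < 0.05
on both marginals) and against a maximum-likelihood NB regression on a
single-unit linear-trend case.

### Counterfactual prediction

For each posterior draw, the random walk is simulated forward
(`gamma_{T+k} = gamma_{T+k-1} + N(0, sigma_gamma)`), the linear trend is
extrapolated, and `pred_reps` (default 5) counts are drawn from the NB —
so the reported median and central 95% interval are full
posterior-predictive quantities including parameter, forecast and counting
uncertainty. Whether the original analysis used plug-in or full predictive
medians is not recoverable; the full predictive median is implemented.

## Anomaly rule

An observation is anomalous iff it falls *strictly* outside the central 95%
predictive interval ("exceeds the boundaries"); a value exactly on a bound
is not flagged (switchable, `strict=False`). Decreases are quantified as
`pred_median - observed` and against both interval bounds
(`pred_lo - observed`, `pred_hi - observed`), the bracketed plausible loss.
Regional aggregates sum these deltas over flagged decreases only. No
multiple-testing correction is applied across provinces — the per-province
false-flag rate is the nominal tail mass (~2.5% per side), which the
calibration tests verify empirically.

## Model selection

Leave-one-**observation**-out (one province-year cell) expected log
predictive density. The estimator is PSIS importance sampling over the
posterior draws; cells whose Pareto tail index exceeds 0.7 are re-estimated
by an exact refit without that cell, and panels of at most 200 cells skip
importance sampling and refit throughout. Ranking is elpd-descending with
ties broken toward fewer effective parameters (`p_loo`), then label, so
candidate order cannot matter. The default candidate set spans linear-only,
RW-only, RW+linear, and the three intercept structures; non-converged
candidates are excluded and reported, never selected.

## Synthetic data generator

`SimulationConfig` defaults define the study conditions the package is
tested under:

- 6 regions with (9, 4, 12, 8, 7, 10) provinces — 50 in total, the actual
  region sizes of the Northern/Central-Italian study area;
- years 2011–2021, training cutoff 2019;
- `alpha = log 3000`, `sigma_u = 0.25`, `sigma_v = 0.35`: counts roughly
  1,100–9,600 across provinces;
- `beta = log 0.96` (~4%/year decline, matching the documented long-term
  fall in hunters), `sigma_gamma = 0.03`;
- `theta = 1000`: near-Poisson, consistent with the tight counterfactual
  intervals (~±3%) real license counts support. Parameter-recovery
  experiments override `theta = 20` to exercise a strongly overdispersed
  regime;
- anomalies: 30% of provinces (≈15/50, matching the observed 14–15) receive
  a multiplicative post-period drop
  `d_p = 0.05 + 0.25 e_p/100 + N(0, 0.08)` clipped to [0, 0.35], where
  `e_p ~ U(0, 60)` percent is the first post-year's excess mortality. The
  implied drop–mortality correlation is ~0.47 (`implied_drop_mortality_corr`),
  i.e. a rank correlation near the observed 0.5. Drops are multiplicative
  because observed percentage decreases are of the same order across very
  different province sizes.
- covariates for later post years are drawn independently, but drops stay
  tied to the *first* post year — attrition concentrated in the first
  epidemic wave persisting into later seasons (the harvesting-effect
  pattern), so lagged pairings are informative in the synthetic world too.

The generator records ground truth including the *assignment* of anomalies
separately from realized drop sizes (the drop line can clip to exactly 0).

What the generator does **not** emulate: age-structured hunter demography,
spatial autocorrelation between neighbouring provinces, registry reporting
artefacts, and policy shocks that hit specific regions in specific years.
Passing calibration tests therefore demonstrate internal consistency of the
method under its own assumptions, not robustness to violations of them.

## Numerical and design choices

- **Missingness**: absent rows, never zeros (a province that reported
  nothing is not a province with zero hunters); fitting requires at least
  3 observed training years per province; anomaly records for provinces
  without an observed post-period count are skipped and reported.
- **Years** label the season's opening (season 2020/2021 → 2020).
- **Spearman** uses midranks plus Pearson-on-ranks, not the 6Σd² shortcut,
  because the mortality covariate is printed in whole percentage points and
  ties are common; constant vectors are an explicit error. The default
  pairing policy uses flagged-decrease provinces only (the policy that
  reproduces the published 2020 value exactly); an all-provinces policy is
  available.
- **Determinism**: every source of randomness (generator, chains,
  forward simulation, predictive draws) descends from explicit seeds;
  rerunning a pipeline with the same seed is byte-identical.
- **Degenerate inputs**: intercept-only candidates are permitted as
  baselines; single-region/single-province panels collapse the
  corresponding effects to zero via the constraints.

## Problem sizes in the test-suite experiments

Calibration experiments use 20 replicate 50-province fits (parameter
recovery and predictive coverage, ~2,000 held-out province-years pooled),
3 replicates for detection power (~100 affected large-province cases),
20 replicates of 24-province panels for selection consistency, and a
40-cell panel for the PSIS-vs-exact-refit comparison — sizes chosen so the
Monte-Carlo error of each proportion is small relative to its acceptance
margin while a full run stays in the minutes range on one CPU.

## Known limitations

- The sampler is random-walk based; for panels far larger than a few
  hundred units a gradient-based sampler would scale better.
- PSIS effective-sample-size correction uses unit relative efficiency;
  slightly optimistic k-hat for very autocorrelated chains.
- The published 2021-season mortality correlation (−0.62) is not exactly
  recoverable from the printed per-province values under any tie
  convention (midranks give −0.63); the published lagged 2021-vs-2020
  value (0.43) requires first-wave mortality for two provinces absent from
  the printed 2020 season. Both are therefore documented but not treated
  as reproduction targets; the in-package lagged computation on the 13
  provinces printed in both seasons gives 0.52.
- One region's published 2021 total (3,904) is inconsistent with the sum of
  its own published per-province rows (2,208); the aggregation operation
  follows the row-sum definition, which reproduces the corresponding 2020
  total exactly.
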