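# huntwatch

Counterfactual anomaly detection for annual license-count panels — built for
the question of whether the COVID-19 pandemic accelerated the long-running
decline of recreational hunting in Northern Italy, and reusable for any
province-level annual count registry with a pre/post design.

Recreational hunters perform most ungulate monitoring and culling in Italy,
so a sudden drop in license renewals is a wildlife-management problem, not
just a statistic. The 2020 and 2021 hunting seasons opened during a pandemic
whose mortality burden varied sharply across provinces, which makes the
setting a natural experiment: if COVID-19 pushed hunters out, the provinces
hit hardest should show the largest shortfalls relative to their own
pre-pandemic trend.

## The model

For province $p$ in region $r(p)$ and season-year $t$, license counts are
modelled as overdispersed counts with a hierarchical log-linear trend:

$$y_{p,t} \sim \mathrm{NegBin}(\mu_{p,t}, \theta), \qquad
\mathrm{Var}(y) = \mu + \mu^2/\theta$$

$$\log \mu_{p,t} = \alpha + u_{r(p)} + v_p + \beta\,(t - t_0) + \gamma_t$$

with region effects $u_r$ (sum to zero), province effects $v_p$ nested in
regions (sum to zero within region), a linear year trend $\beta$, and a
first-order random-walk year effect $\gamma_t$ ($\gamma_{t_0}=0$,
innovations $\mathcal N(0,\sigma_\gamma)$) that absorbs non-linear common
shocks. Inference is MCMC (adaptive Metropolis-within-Gibbs, numba-compiled,
2+ chains, split-$\hat R$/ESS diagnostics). The pipeline then:

1. **fits** the model to pre-period years only (2011–2019);
2. **projects** posterior-predictive counterfactuals into the post-period
   (the random walk is simulated forward, a new count is drawn per draw, so
   medians and central 95% intervals are full predictive quantities);
3. **flags** observed counts strictly outside the 95% interval and
   quantifies each anomalous decrease against the predictive median and
   both interval bounds;
4. **aggregates** flagged decreases by region; and
5. **correlates** (tie-aware Spearman, midranks + Pearson-on-ranks) each
   province's absolute decrease with its excess mortality — the percentage
   increase of the season-year's deaths over the 2015–2019 mean — including
   lagged pairings.

Candidate structures (linear only, RW only, RW+linear, region-only /
province-only / nested intercepts) are compared by leave-one-observation-out
cross-validation (PSIS importance sampling with exact refit fallback).

A synthetic-panel generator (`huntwatch.simulate`) reproduces the assumed
data-generating process — 50 provinces in 6 regions, counts ~1,100–9,600, a
~4%/year decline, and post-period multiplicative drops (0–30%) coupled to a
simulated mortality covariate — with full ground truth, so calibration,
power and model-selection behaviour are all testable without the original
registries.

## Worked example

The package bundles the published reference values for the 29
province-seasons with anomalous decreases (observed counts, counterfactual
medians and 95% bounds, mortality covariates). Feeding them through the
anomaly operations:

```python
import huntwatch as hw
from huntwatch.datasets import (load_reference_anomalies, reference_panel,
                                reference_predictive_summary, reference_covariates)

ref = load_reference_anomalies()
records = hw.flag_anomalies(reference_predictive_summary(ref), reference_panel(ref), 2020)
print(records.query("province == 'Milan'")[["observed", "pred_median", "delta_median", "delta_lo", "delta_hi"]])
#    observed  pred_median  delta_median  delta_lo  delta_hi
# 0      5067       5640.0         573.0     396.0     756.0

lom = hw.aggregate_region(records, "Lombardy", 2020)
print(lom.sum_delta_median, (lom.sum_delta_lo, lom.sum_delta_hi))
# 2720.0 (1788.0, 3688.0)

print(hw.associate(records, reference_covariates(), 2020))
# AssociationResult(anomaly_year=2020, covariate_year=2020, n=14,
#                   rho=0.5242303465790682, policy='flagged')
```

Milan enrolled 5,067 hunters in the 2020/2021 season against a predicted
5,640 (5,463–5,823): 573 fewer than the most likely counterfactual, with a
plausible loss of 396–756. Lombardy's flagged provinces sum to 2,720 missing
hunters, and across the 14 flagged provinces the absolute decrease
rank-correlates with 2020 excess mortality at $\rho = 0.52$.

An end-to-end synthetic run from the shell:

```bash
huntwatch run --seed 7 --out out/          # simulate -> fit -> detect -> associate
huntwatch report --bundle out/             # human-readable summary
```

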