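# binaryiv

Instrumental-variable estimation when **both the outcome and the exposure
are dichotomous** — the standard situation in pharmacoepidemiology, where a
binary drug exposure T may cause a binary adverse event Y, and an
unmeasured confounder X_u drives both treatment uptake and the event. The
package is for biostatisticians and methods researchers who want to fit,
compare, or stress-test the two nonlinear IV estimators most often
proposed for this setting, using the physician's prescribing preference as
the instrument.

## Model and estimators

The structural models are double logistic:

    P(Y=1 | T, X1, X2, Xu) = expit(β₀ + Tβ_t + X1β₁ + X2β₂ + Xuβ_u)
    P(T=1 | Z, X1, X2, Xu) = expit(α₀ + Zα_z + X1α₁ + X2α₂ + Xu)

The estimand is β_t, the conditional log odds ratio of treatment. Because
X_u is unobserved, the naive logistic fit of Y on (1, T, X1, X2) is
biased. The instrument Z is the physician's prescribing preference,
proxied from the prescribing history by either the previous patient's
treatment (`zstar`) or the running proportion of the physician's earlier
patients treated (`pr`). Estimators:

* **2SRI** (two-stage residual inclusion): regress T on
  (1, Z, X1, X2), then regress Y on (1, T, X1, X2, Û) where
  Û = T − expit(ŵ′α̂) is the first-stage residual acting as a control
  function. The reported covariance is the three-term two-step sandwich
  A₂₂⁻¹S₂A₂₂⁻¹′/n + … that propagates first-stage estimation noise.
* **IV-GMM**: solve the exactly identified sample moments
  (1/n)Σ eᵢwᵢ = 0 with e = Y − expit(x′β), w = (1, Z, X1, X2);
  two-step optimal weighting for the covariance.
* Oracle ("true") and naive ("conventional") logistic fits as benchmarks.

A synthetic-cohort generator (physician-clustered patients, Bernoulli
preference, normal covariates and confounder), closed-form instrument-
strength and confounding-level diagnostics, a first-stage F-equivalent,
and a Monte-Carlo study engine with the filtering and evaluation criteria
(relative bias, MC/asymptotic sd, rMSE, non-coverage) complete the
package. See `docs/methods.md` for the full methodology.

## Worked example

```python
import binaryiv as biv
from binaryiv.diagnostics import scenario_diagnostics

cfg = biv.rare_event_config("strong", "high", n=30000, seed=1)
cohort = biv.attach_proxies(biv.simulate_cohort(cfg, seed=1))
sample = cohort.estimation_sample()        # drops each physician's first patient

diag = scenario_diagnostics(cfg, cohort)
print("instrument strength Corr(Z,T*) = %.3f" % diag["corr_Tstar_Z"])
print("confounding level  Corr(Xu,T*) = %.3f" % diag["confounding_level"])
print("first-stage F-equivalent      = %.1f" % diag["first_stage_F"])

for name, fit in [
    ("oracle", biv.fit_true(sample)),
    ("naive", biv.fit_conventional(sample)),
    ("2SRI", biv.fit_2sri(sample, "pr").second),
    ("GMM", biv.fit_gmm(sample, "pr")),
]:
    lo, hi = fit.ci[1]
    print(f"{name:7s} beta_t = {fit.beta_t:5.3f}  95% CI [{lo:5.3f}, {hi:5.3f}]")
```

Output:

```
instrument strength Corr(Z,T*) = 0.444
confounding level  Corr(Xu,T*) = 0.485
first-stage F-equivalent      = 281.7
oracle  beta_t = 3.017  95% CI [2.859, 3.175]
naive   beta_t = 3.906  95% CI [3.758, 4.055]
2SRI    beta_t = 3.121  95% CI [1.807, 4.436]
GMM     beta_t = 2.832  95% CI [1.982, 3.682]
```

The cohort was generated with β_t = 3 and heavy confounding (σ_u = 1.5).
The naive fit overstates the treatment log odds ratio by ~30% and its
interval misses the truth entirely; 2SRI recovers it with a wider interval
that reflects first-stage uncertainty; the single-cohort GMM estimate is
close here but is the least stable of the methods across replications
(see the study engine below). The F-equivalent (~282 on this cohort; the
statistic is noisy replication to replication) confirms a strong
instrument.

A full Monte-Carlo comparison over a scenario grid:

```sh
binaryiv study --grid grid.yaml --instrument pr --ns 200 --seed 42 --out results/
binaryiv diagnose --config grid.yaml
binaryiv fit --method 2sri --instrument pr --input cohort.csv --out fit.json
```

where `grid.yaml` lists cells such as
`{strength: strong, confounding: high, n: 30000}`.

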