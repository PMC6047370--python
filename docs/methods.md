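# Methods

## Problem and model

`binaryiv` studies the estimation of a treatment effect on a binary outcome
when the binary exposure is endogenous: an unmeasured patient-level
confounder `Xu` raises both the probability of being treated and the
probability of the adverse event. The structural outcome model is logistic,

    P(Y = 1 | T, X1, X2, Xu) = expit(b0 + T*bt + X1*b1 + X2*b2 + Xu*bu),

and the treatment-choice model is logistic in an instrument Z and the same
covariates,

    P(T = 1 | Z, X1, X2, Xu) = expit(a0 + Z*az + X1*a1 + X2*a2 + Xu).

The target of inference is `bt`, the conditional log odds ratio of
treatment. A fit of the outcome model that simply omits `Xu`
(the *conventional* fit) is biased; the package quantifies that bias and
the degree to which instrumental-variable estimators remove it.

The instrument is the prescribing preference of the treating physician: a
latent binary tendency `PP ~ Bernoulli(p)` shared by all patients of a
physician, independent of the patient's covariates and confounder, and
affecting the outcome only through the prescribed treatment. Because `PP`
is latent in practice, two observable proxies are built from the
prescribing history:

* `Zstar` — the treatment given to the physician's immediately preceding
  patient;
* `pr` — the proportion of the physician's *earlier* patients (within the
  observation window) who received the treatment of interest.

Both proxies are undefined for the first patient of each physician; those
patients are excluded from estimation samples rather than imputed (with
100 patients per physician this drops 1% of rows). Patients are ordered by
generation order; no calendar time is modelled.

## Estimators

* **Oracle ("true") fit** — logistic ML of Y on (1, T, X1, X2, Xu).
  Available only on simulated data; the benchmark all other methods are
  judged against.
* **Conventional fit** — logistic ML of Y on (1, T, X1, X2).
* **2SRI** — stage 1 regresses T on (1, proxy, X1, X2); stage 2 regresses
  Y on (1, T, X1, X2, U) where U is the stage-1 residual `T - expit(w'a)`.
  Both stages minimize the least-squares criterion with a logistic mean by
  default (`stage_loss="nls"`), because the two-step covariance below is
  derived under that loss; a logistic-ML variant of both stages is
  available. The residual column acts as a control function: it carries the
  part of treatment variation attributable to the confounder, so its
  coefficient plays the role of `bu`. Because the confounder enters the
  treatment index non-additively (inside the logistic link), the control
  function is only an approximation and a residual bias remains; it shrinks
  as the instrument strengthens.
* **IV-GMM** — solves the sample moment conditions E[e·w] = 0 with
  e = Y - expit(x'beta), x = (1, T, X1, X2) and w = (1, proxy, X1, X2). The
  system is exactly identified, so the point estimate is invariant to the
  weighting matrix; the implementation minimizes the identity-weighted
  quadratic form by multistart BFGS (starting from the conventional-fit
  coefficients and from zero, gradient tolerance 1e-8, at most 500
  iterations) and then polishes with a Newton solve of the moment
  equations. A fit is declared converged only when the sup-norm of the
  sample moments is below 1e-6. The two-step optimal weight
  (inverse of the moment covariance at the first-pass estimate) enters the
  reported covariance `(G' S^-1 G)^-1 / n`. Singular moment-covariance or
  Jacobian matrices (condition number above 1e12) flag the fit instead of
  silently dropping it.

### Two-step sandwich covariance for 2SRI

Software covariances from the second stage ignore that the residual column
is itself estimated. The package therefore assembles the three-term
sequential-estimation covariance

    Var(b) = (A22^-1 S2 A22^-1' + A22^-1 A21 A11^-1 S1 A11^-1' A21' A22^-1'
              - A22^-1 S21 A11^-1' A21' A22^-1') / n

from plug-in blocks built with the logistic density weights
`g = Pa(1-Pa)` (stage 1) and `h = Pb(1-Pb)` (stage 2); `A21` carries the
residual coefficient `bu` and squared stage-2 weights `h^2`. The result is
symmetrized as `(V + V')/2`. The first term is the one-step
heteroscedasticity-robust sandwich of stage 2 (recovered exactly when the
cross blocks are zeroed); the other two propagate stage-1 noise. At
n = 30000 the square root of the averaged sandwich variance of `bt` tracks
the Monte-Carlo standard deviation closely and 2SRI non-coverage stays
near the nominal 5% (both verified by the 200-replication study runs in
the test suite), and the patient-level bootstrap sd agrees with the
sandwich sd within 15%.

### First-stage F-equivalent

With a single instrument, the linear-IV convention reports the first-stage
F = squared instrument t-statistic. The treatment model here is logistic,
so `first_stage_F` offers two Wald analogues:

* `loss="nls"` (default) — squared t from the logistic-mean NLS fit with
  the conventional least-squares covariance `s^2 (J'J)^-1`, the exact
  analogue of the OLS first-stage F (which likewise pools the residual
  variance). With a binary treatment the pooled variance is wrong
  (heteroscedasticity), so this statistic is anti-conservative under a
  null instrument — exactly as the homoscedastic linear F is — but it is
  the convention-faithful diagnostic and is what the Monte-Carlo F tables
  report.
* `loss="ml"` — Wald z² from the logistic ML fit; chi-square(1)
  calibrated under a null (permuted) instrument. Use this variant for
  testing instrument relevance.

A likelihood-ratio variant (`method="lr"`) is also provided.

## Synthetic-data generator

The generator emulates a pharmacoepidemiological cohort: physicians with
100 patients each; covariates X1 ~ N(-2,1), X2 ~ N(-3,1); confounder
Xu ~ N(0, sigma_u); preference PP ~ Bernoulli(0.7) at the physician level;
treatment and outcome drawn from the logistic indices above. Two presets
fix the intercepts:

* **rare** (default): a = (0.2, az, 2, 1.2), b = (-0.6, 3, 1, 1, 1) — a
  newly marketed drug with a rare adverse event. Measured at n = 30000 the
  exposure prevalence runs from ~1.5% (weak instrument, low confounding)
  to ~6.9% (strong, high) and the event prevalence from ~1.7% to ~5.1%;
  the central cells sit in the 2-6% / <5% band.
* **balanced**: only the intercepts change (a0 = 5, b0 = -2.3), giving
  ~26-45% exposure with events still below 6%.

Instrument strength takes az in {1, 2, 3} (weak/mod/strong) and
confounding sigma_u in {0.5, 1, 1.5} (low/med/high). Closed forms for
Corr(T,Z), Corr(Z,T*) and Corr(Xu,T*) (T* the latent treatment index)
express these levels analytically and are verified against 10^6-draw
sample correlations.

Randomness uses one `SeedSequence` per cohort split into per-variable
substreams in a fixed documented order, so cohorts are bit-reproducible
and extending the generator cannot perturb existing draws. Monte-Carlo
replication r of a study uses the seed sequence `(root, r)`, making grid
results independent of any parallel worker count.

The generator draws each outcome as Bernoulli(expit(index)); the
distributionally identical latent-index construction
`Y = 1(index - eps > 0)` with standard-logistic `eps` is implemented
alongside and the equivalence of the two is tested by two-sample
proportion comparison.

What the generator does *not* emulate: time-varying preference or
change points, unequal panel sizes, covariate-confounder correlation,
correlated or clustered outcomes beyond the shared preference, geographic
or calendar-time instruments, and measurement error. Passing tests
therefore show that the estimators behave as intended under an idealized
preference instrument with clean exclusion; they do not certify behaviour
under preference drift or instrument-confounder correlation in real
claims data.

## Monte-Carlo study and filtering

For each scenario the engine simulates `ns` cohorts, fits the requested
methods on the proxy-valid sample of each, and summarizes the treatment
coefficient by relative bias (%), Monte-Carlo sd, averaged asymptotic sd,
rMSE, and lower/upper non-coverage of 95% Wald intervals (strict
inequalities; totals printed as proportions). Replications where GMM fails
are removed for *all* methods, so every method is summarized over the same
samples; afterwards a method's replication is dropped as an outlier when
|relative bias| exceeds 100% or its variance estimate is non-finite. All
drops are counted per method and reported. A scenario with more than half
of its replications unusable is flagged.

Replication budgets are a deliberate trade-off: the default is ns = 200
(100 for the balanced regime) with tolerance checks scaled by the
Monte-Carlo standard error of the reduced run; a 1000-replication run
reproduces the reference tables more tightly and is available by setting
`ns` in the scenario grid.

## Numerical choices

* Logistic ML via IRLS (statsmodels GLM), tolerance 1e-10, 100 iterations;
  separation or |coef| > 50 marks the fit non-converged.
* NLS stages via Levenberg-Marquardt with the analytic Jacobian, warm
  started at the ML solution, tolerances 1e-12.
* Matrix inversions guarded by condition-number checks (1e12); the
  sandwich raises a singular-design error with the condition number.
* Wald intervals at the 95% nominal level throughout.
* Bootstrap resamples patients within the estimation sample by default
  (physician-block resampling available); more than 20% failed refits
  aborts the bootstrap.

## Known limitations and observed behaviour

* A correctly solved exactly identified IV-GMM has a *small* bias here at
  rare event rates (measured relative bias ≈ 3-4% at n = 30000, high
  confounding, strong instrument) but a much larger Monte-Carlo sd than
  the conventional fit, and its moment system becomes ill-conditioned
  under weak instruments — in the weak-instrument cells roughly half of
  the replications fail the 1e-6 moment tolerance or produce outlier
  variance estimates. The objective surface is numerically flat (moments
  of order 1e-4), which is why generic optimizers without a root-solving
  polish tend to stall near their starting values; fits are validated by
  the sup-norm of the moments, never by the optimizer's own status alone.
* 2SRI inherits first-stage noise: its sd is several times the
  conventional fit's, and under weak instruments its residual bias can
  exceed the confounding bias it removes. Under high confounding with a
  strong instrument it is nearly unbiased with near-nominal coverage —
  the configuration in which an IV analysis is actually warranted.
* The closed-form Corr(T,Z) freezes covariates at their means and so
  understates the realized treatment-instrument correlation in full
  cohorts; it is a scenario-design quantity, not an estimable diagnostic.
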