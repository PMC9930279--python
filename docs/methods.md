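# Methods

## Model

The package implements a three-state illness-death process observed in
continuous time from a common origin (hospital discharge after an index
fracture): state 1 = event-free, state 2 = intermediate non-terminal event
(refracture), state 3 = death. Transitions 1→2 and 1→3 run on the time
scale since the origin; transition 2→3 runs on the time since entry into
state 2 (semi-Markov clock reset). Each transition intensity is a Weibull
proportional-hazards model

h(t) = α λ t^(α−1) · exp(β_Wo I_Wo + β_Age (Age − Āge)),

where I_Wo indicates women (men are the reference), age is centered at the
cohort mean Āge to decorrelate the intercept-like scale λ from β_Age and
improve MCMC mixing. Note the rate-like parameterization: the baseline
cumulative hazard is H₀(t) = λ t^α, so λ is **not** the textbook Weibull
scale σ = (1/λ)^(1/α). Optionally the 2→3 intensity may include the entry
time t₁₂ as a covariate (β_t12); a coefficient near zero supports the
homogeneous clock-reset specification.

Assumptions: exactly observed event times (no interval censoring), purely
administrative right censoring independent of everything, no left
truncation, proportional hazards in sex and age, and conditional
independence of the cause-specific transitions given covariates. The
centering constant travels with the data and the fitted model: predictions
always use the training value.

## Likelihood

Each subject contributes a right-censored observation to the 1→2 and 1→3
datasets (death without the intermediate event censors the 1→2 time at the
death time; administrative censoring censors both) and, if they entered
state 2, an observation to the 2→3 dataset on the reset clock. The total
log-likelihood is the sum of three standard right-censored Weibull PH terms
Σ δ log h(t) − H(t) and factorizes over transitions, so the three blocks
are fitted independently.

## Priors and sampling

Priors are vague and independent: Normal(0, 100²) on each regression
coefficient and Gamma(shape 0.01, rate 0.01) on each Weibull shape and
scale (mean 1, variance 100; Gamma is parameterized by shape and **rate**).
Sampling is adaptive random-walk Metropolis on (log α, log λ, β…) with the
log-Jacobian in the target. During burn-in the proposal covariance tracks
the chain's running covariance (scaled 2.38²/d with a 1e-9 jitter,
refreshed every 50 iterations) and the global step size is tuned by
Robbins–Monro (rate (1+i)^−0.6) toward 23.4% acceptance; after burn-in the
proposal is frozen, so retained draws target the exact posterior. Defaults:
3 chains, 10,000 retained iterations after 5,000 burn-in, no thinning;
chains start from exponential moment estimates (α = 1, λ = events/exposure,
β = 0) with 0.05-scale jitter. Every run requires an explicit seed;
per-transition and per-chain streams are spawned from it. Convergence is
summarized by split-R̂ and bulk ESS (arviz), flagging R̂ > 1.01.

## Probability functionals and quadrature

p11 and p22 are closed-form in the Weibull cumulative hazards. p12 and the
cumulative incidences are one-dimensional integrals computed with fixed
64-node Gauss–Legendre quadrature. When the lower limit is 0 the integrand
contains u^(α−1) factors that are singular (α < 1) or have unbounded
derivatives (non-integer α); the substitution u = t·v^k with
k = max(2, 3/α_min) makes the transformed integrand at least twice
differentiable at the origin. Worst-case absolute error measured against
512-node refinement over random parameter sets (α ∈ [0.3, 2.5],
λ ∈ [0.02, 1.2], horizons up to 9 years) is below 1e-6, which is also the
tolerance asserted for the conservation identity p11 + p12 + p13 = 1.

Posterior uncertainty is propagated by evaluating each functional at every
retained draw (vectorized by broadcasting draw columns against quadrature
nodes) and summarizing pointwise with the mean and equal-tailed 2.5/97.5
percentiles. The interval type is a choice — the source analysis does not
state whether its 0.95 intervals are equal-tailed or HPD — as is the
default reporting grid (0–10 years, step 0.1).

### Plug-in versus posterior mean

`mortality_table` and the prediction methods of the fitted estimator
average the functional over draws (a posterior mean). When only printed
posterior means are available (`reference_params()`), the functionals are
evaluated once at those means — a plug-in estimate that differs from the
posterior mean of the functional by a Jensen gap. For the reference
estimates the gap is negligible for the 1→2 and 1→3 quantities (posterior
SDs ≲ 1.5% of the means) but reaches ~0.1 percentage points on the one-year
2→3 probabilities for men (wider 2→3 posterior: only ~7% of subjects enter
state 2), and the printed reference values cannot be matched more closely
than that from means and SDs alone, since the joint posterior correlation
structure is not published.

## Synthetic cohorts

The generator draws covariates (women with probability 0.748; ages uniform
within the four reported bands — 12.4% in 65–75, 43.6% in 75–85, 40.6% in
85–95, 3.4% in 95–105 — giving mean ≈ 83.5, or optionally Normal), then
latent 1→2 and 1→3 times by inverse transform, an administrative censoring
time C = 9 − U(0, 8) years (uniform accrual over 8 years, common closing
date at 9; chosen to give a reverse-Kaplan–Meier median follow-up of ≈ 5
years), and, for subjects whose refracture precedes min(death, C), a 2→3
time on the reset clock. The latent-failure-time construction with
independent causes reproduces exactly the cause-specific hazards of the
model — which is all that the observed data identify — so it is a valid
oracle for every functional; it is not a claim about the real-world joint
distribution of the latent times.

What the generator does *not* emulate: loss to follow-up, registry
linkage artifacts, death-certificate lag, secular trends, covariates beyond
sex and age, or frailty/unobserved heterogeneity. Passing recovery and
agreement tests on synthetic data therefore validates the estimation and
probability machinery under the model's own assumptions; it cannot detect
misspecification that real registry data might exhibit.

`mc_probability` (the Monte-Carlo oracle) simulates uncensored latent
trajectories for a fixed covariate profile and reports the empirical
frequency of the queried state occupation among trajectories satisfying the
conditioning event, with binomial standard error; quadrature results are
required to agree within 3 standard errors at 10⁶ trajectories.

## Nonparametric checks

Nelson–Aalen cumulative hazards (jumps d/n at event times, events before
censorings at ties) are computed per cause-specific dataset and
cross-checked in the tests against an independent survival-analysis library.
The Aalen–Johansen estimator builds the product integral of the empirical
3×3 intensity increments; with no intermediate events it collapses exactly
to Kaplan–Meier. Because censoring is independent of covariates and
trajectory, the AJ state-occupation probabilities p_1j(0, t) are consistent
here even though the process is semi-Markov and the population is a
covariate mixture; `model_check` therefore compares them with the
covariate-averaged parametric curves and reports the maximum absolute
discrepancy per curve. On 20,000 simulated subjects the sup-discrepancy
over [0, 5] years is below 0.02.

## Numerical and design choices

- Time unit is years (floating point); a reader option divides integer day
  counts by 365.25. Tied refracture/terminal times are rejected by default;
  a `tie_offset` reader option (suggested 0.5/365.25) breaks ties instead,
  keeping the 2→3 likelihood finite.
- Degenerate inputs fail loudly: empty cohorts, transitions with zero
  events (named in the error), posteriors with fewer than 100 draws,
  single-chain diagnostics.
- `median_followup` in cohort summaries is the reverse Kaplan–Meier median
  (the censoring-distribution median), the standard definition when
  mortality is high.
- Problem sizes used by the test suite (10,000 subjects for MCMC recovery,
  20,000 for the nonparametric check, 10⁶ Monte-Carlo trajectories) were
  chosen so that Monte-Carlo and posterior uncertainty are small relative
  to the asserted tolerances while the whole suite runs in well under a
  minute of sampling time.

## Known limitations

- Single baseline family (Weibull); no Gompertz, piecewise-exponential or
  spline baselines, no stratified or time-varying effects.
- No left truncation or interval censoring; no reversible transitions or
  additional states.
- The adaptive sampler is serial per chain; for very large cohorts a
  gradient-based sampler would mix faster per second.
- Aalen–Johansen variance (Greenwood-type) is not implemented; the step
  functions carry variance slots only for Nelson–Aalen.
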