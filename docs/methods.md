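# Methods

`nccjoint` implements joint models for a longitudinal biomarker and
competing-risks survival outcomes when the biomarker is only measured inside
a nested case-control (NCC) sub-cohort. This note records the model, the
estimators, the numerical choices, and what the synthetic-data experiments
do and do not demonstrate.

## Model

**Longitudinal sub-model.** For subject *i* with biomarker values
*Y<sub>ij</sub>* at times *t<sub>ij</sub>*, a generalized linear mixed model
with a random intercept:

    g(E[Y_ij | b_i]) = X_i^(1) γ + b_i,      b_i ~ N(0, θ²)

Two family/link pairs are supported: Gaussian with identity link (residual
SD σ) and negative binomial with log link (dispersion φ, conditional
variance μ + φμ²) for overdispersed counts such as read-count-derived
abundances. The fixed design `X^(1)` holds the observation time (slope
γ_time) and optional baseline covariates.

**Survival sub-model.** Cause-specific hazards for K competing events,
driven by the current (noise-free) trajectory value:

    λ_k(t | b_i) = λ_0k(t) · exp( β_k · g⁻¹(X_i^(1)(t) γ + b_i) + α_kᵀ X_i^(2) )

with piecewise-constant baselines λ_0k(t) = Σ_q ξ_kq 1{v_{q−1} < t ≤ v_q}
on a shared knot grid (half-open pieces; an event at t = v_q belongs to
piece q). β_k — the association between the biomarker trajectory and event
k — is the parameter of interest. With K = 1 the model is an ordinary
piecewise-exponential proportional-hazards model.

**Parameters.** φ-vector (packed, all unconstrained): γ; log σ or log φ;
log θ (log-Cholesky of the 1×1 random-effect covariance); β₁..β_K; α_k; and
log ξ_kq. Baseline heights are estimated jointly with everything else by
maximizing the same likelihood; no profiling. SEs for the variance-type
parameters are reported on the log scale.

## Likelihood variants

All variants marginalize the random intercept and share one optimizer
(L-BFGS-B on the packed vector, analytic gradients on the Gaussian path):

- **oracle** — every subject contributes longitudinal *and* survival terms
  (full-cohort benchmark, available only in simulation);
- **fjm_ncc** — all subjects contribute survival terms; longitudinal terms
  only for sub-cohort members (their absence elsewhere is missing at
  random by design, so the skipped factor is exactly 1);
- **wjm_ncc** — sub-cohort members only, each term weighted by the inverse
  probability of inclusion; valid when full-cohort covariates are
  unavailable;
- **naive_jm** — sub-cohort members only, unweighted. This is a *comparator*
  that approximates fitting a classical joint model to the sub-cohort as if
  it were a cohort; it is biased by construction because NCC sampling
  distorts the event rate to 1/(m+1). It uses the same piecewise baseline
  as the other variants rather than a spline.

Two identities pin the variants together and are tested exactly:
fjm_ncc on a fully-observed cohort equals oracle term by term, and wjm_ncc
with unit weights equals naive_jm.

## NCC sampling and weights

Cases are the `n_cases` earliest events; the largest case event time
censors everyone else (administrative censoring). For each case, `m`
controls are drawn uniformly without replacement from the risk set —
subjects event-free and uncensored at the case's event time, matching the
case exactly on the matching factors, the case itself excluded, future
cases allowed. Ties in event times break by subject id for determinism.
When a risk set is smaller than m, all members are taken and both m_l and
n_l are recorded so the weights stay valid.

A control's weight inverts its probability of ever entering the sub-cohort:
w_i = [1 − Π_{l∈S_i}(1 − m_l/n_l)]⁻¹, where S_i ranges over every case
whose risk set contained subject i — *eligibility*, not actual draws, which
is why the sampler records full risk-set membership. Cases have w_i = 1
even when they were eligible as controls earlier. The weighted-control sum
is a Horvitz–Thompson estimate of the number of event-free cohort members,
which the tests check on simulated cohorts.

## Numerical integration of the random effect

The marginal likelihood needs ∫ f(T,δ|b) f(Y|b) φ_θ(b) db per subject. A
Gauss–Hermite rule centered at zero with the prior scale is badly matched
here: with five observations and the replication variances the posterior of
b is ≈3.4× narrower than its prior, and such a rule still errs by ~3×10⁻³
per subject at 25 nodes. The package therefore adapts the rule to the
integrand:

- **Gaussian/identity path** (vectorized engine): the longitudinal density
  times the prior is itself Gaussian in b, so that product is integrated
  *exactly* (the compound-symmetry marginal, in closed form) and only the
  survival factor exp(F b − Σ_k D_k e^{β_k b}) is averaged over the exact
  posterior N(μ_i, s_i²) with a Gauss–Hermite rule matched to that kernel.
  The remaining integrand is an entire function with mild curvature, and
  15 nodes (the default) reach near machine precision. The gradient is
  analytic, including the dependence of the kernel (μ_i, s_i) on the
  parameters, and per-subject score vectors fall out of the same pass.
- **Generic path** (any family; used by the negative binomial and as an
  independent cross-check of the fast engine): Laplace-adapted Gauss–
  Hermite — nodes centered at the mode of the full integrand and scaled by
  its curvature — with cumulative hazards by fixed-order Gauss–Legendre
  (default order 7) within each baseline piece; the identity-link
  time-linear case instead uses the exact per-piece closed form
  ξ e^{β_k b + αx}(e^{β_k γ v_hi} − e^{β_k γ v_lo})/(β_k γ).

The two engines agree to ~10⁻¹⁴ on shared configurations, which the tests
assert, together with 15-vs-25-node stability (<10⁻⁵ per subject) and
agreement with adaptive dense integration.

## Optimization and initialization

Quasi-Newton (L-BFGS-B), maximum 500 iterations, tight relative-decrease
tolerance (1e-11) and gradient tolerance 1e-6. Starting values are
moment-based: γ and σ from pooled least squares and a within/between
variance decomposition of the longitudinal data, θ from the between-subject
variance of mean residuals, ξ from cause-specific events per unit of
person-time per piece, β = α = 0. Non-convergence is a flagged result, not
an exception. Refitting from a solution terminates within one iteration
(tested).

## Covariance estimation

- **Fisher**: inverse of the negative Hessian of the fitted variant's total
  log-likelihood (central finite differences of the analytic gradient,
  relative step 10⁻⁵; second differences of the value on the generic path).
- **Sandwich** (for the weighted likelihood, whose weighted score is not an
  ordinary likelihood score): bread⁻¹·meat·bread⁻¹ with the negative
  Hessian of the weighted log-likelihood as bread and the mean-centered
  outer-product sum of per-subject weighted scores as meat. Written with
  per-subject normalizations on both factors, the sample-size scalings
  cancel, so this unscaled composition is directly the covariance of the
  estimates; the implementation is pinned by an exact closed-form check on
  a weighted-mean toy problem. Point estimates are identical under either
  SE method; only the uncertainty differs.

Wald z-tests and 95% intervals use the conventional 1.96 multiplier.
Bonferroni adjustment is min(1, p·n).

## Synthetic-data generator

The generator reproduces the replication conditions and doubles as the
package's test bed: Y_ij = γ t_ij + b_0i + ε_ij on the grid (0, 0.1, 0.2,
0.3, 0.4) with γ = 0.1, θ² = 2, σ² = 1; a Bernoulli(0.5) binary covariate
with α = −0.2 on both log-hazards; constant baselines e⁻⁵ and e⁻⁴ for the
two competing events; N = 8000 with the 400 earliest events as cases.
Event times invert the closed-form total cumulative hazard at an
Exponential(1) deviate by bracketed bisection (round-trip residual < 10⁻⁸,
tested against independent adaptive integration); the cause is assigned
with probability proportional to the cause-specific hazards at the drawn
time — equivalent, for these hazards, to taking the minimum of
cause-specific latent times. The hazard acts on the noise-free trajectory
γt + b₀; measurement error enters only the observed series. When
β_k γ < 0 the total hazard can be bounded; subjects whose deviate exceeds
the bound never fail and are recorded with an infinite latent time.

What the generator does *not* emulate: irregular visit schedules,
informative observation times, biomarker missingness within the sub-cohort,
non-Gaussian measurement error in the Gaussian path, covariate-dependent
censoring, or the compositional coupling between taxa in real abundance
tables (scan fixtures spike independent series). Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those violations.

## Replication harness and problem sizes

The evaluation harness repeats simulate → sample → fit and reports Bias,
mean estimated SE, empirical SE (SD across replicates, n−1 denominator),
MSE, mean 95% CI length, empirical coverage, and Wald rejection rates,
excluding (and counting) non-convergent replicates. Replicate r of a cell
uses simulation seed `seed_base + r` and an independent control-sampling
stream, so any cell reruns bit-identically.

Summary quantities stabilize at different rates, and the harness exploits
that: coverage and type-I-error cells use ~400 replicates (Monte-Carlo SD
≈ 0.011 for a 95% coverage proportion), while mean-SE and bias cells use
~200 (per-replicate estimated SEs vary by only a few thousandths). The
acceptance script and test suite use these desk-scale counts with full-size
cohorts (N = 8000); power curves default to a 0.05-step effect grid with
the fine 0.01 grid available through configuration.

## Microbiome preprocessing and the per-taxon scan

Sample-level QC runs before taxon-level QC: samples with more than 10%
missing entries (explicit missingness — zeros are valid abundances) or with
all-zero abundances are dropped; then taxa detected in fewer than 10% of
the *retained* samples or with mean relative abundance below 0.01% are
dropped. The filter is idempotent and the samples-first order is observable
and tested. Downstream association scans take arcsine-square-root
transformed relative abundances as the longitudinal outcome, fit one joint
model per taxon, and Bonferroni-adjust each coefficient's p-values across
taxa; per-taxon non-convergence is recorded without stopping the scan.

## Known limitations

- Random effects are intercept-only; the interface reserves room for
  intercept+slope but v1 does not implement it.
- The naive_jm comparator approximates a spline-baseline joint model with
  the shared piecewise-constant baseline; its bias magnitudes are expected
  to track, not exactly equal, a spline implementation's.
- CLR drops within-set-constant covariates (exact matching factors are
  inestimable in a conditional likelihood) and flags separation rather than
  failing.
- No left truncation, no subdistribution (Fine–Gray) hazards, no Bayesian
  or EM estimation, no multivariate random effects.
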