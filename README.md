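# nccjoint

Joint models for longitudinal biomarkers and competing-risks survival
outcomes under **nested case-control (NCC) sampling**.

## The problem

Large prospective cohorts (think tens of thousands of children followed for
islet autoimmunity, with stool samples banked at every visit) cannot afford
to assay biomarkers — microbiome profiles, metabolomics — for everyone.
The standard compromise is an NCC design: every subject who develops the
outcome becomes a *case*, and for each case a few event-free *controls*,
matched on factors like sex and clinical center, are drawn from its risk
set. Only the sub-cohort's biospecimens are processed.

Analyzing such data correctly is awkward on three fronts at once: the
biomarker is a noisy longitudinal trajectory (not a single measurement),
the outcome may be one of several *competing* events (e.g. which
autoantibody appears first), and the sub-cohort is a biased sample of the
cohort. `nccjoint` addresses all three with a joint model:

- **Longitudinal sub-model** — generalized linear mixed model with a random
  intercept: `g(E[Y_ij | b_i]) = X_i⁽¹⁾γ + b_i`, with Gaussian/identity or
  negative-binomial/log families.
- **Survival sub-model** — cause-specific proportional hazards driven by
  the current trajectory value:
  `λ_k(t|b_i) = λ_0k(t) exp(β_k · g⁻¹(X_i⁽¹⁾(t)γ + b_i) + α_kᵀX_i⁽²⁾)`,
  with piecewise-constant baselines. The `β_k` are the quantities of
  interest.

Two estimators handle the NCC design, both marginalizing the random effect
by adaptive Gauss–Hermite quadrature:

- **fJM-NCC** (`variant="fjm_ncc"`) — full-likelihood: survival and
  covariate terms from the whole cohort, longitudinal terms from the
  sub-cohort (whose absence elsewhere is missing-at-random by design).
- **wJM-NCC** (`variant="wjm_ncc"`) — sub-cohort only, weighting each
  subject by the inverse of its inclusion probability
  `w_i = [1 − Π_{l∈S_i}(1 − m_l/n_l)]⁻¹`, with a robust sandwich
  covariance (a plain Fisher covariance under-states the uncertainty of a
  weighted likelihood, and the package can show you by how much).

Alongside: a full synthetic-cohort simulator, the NCC sampler itself, an
oracle (full-cohort) benchmark, a naive unweighted joint model and a
conditional-logistic-regression comparator, an evaluation harness
(bias/SE/ESE/MSE/CI-length/coverage/power), and microbiome preprocessing
(sample/taxon QC filters, arcsine-square-root transform) with a per-taxon
association scan under Bonferroni correction.

## Worked example

Simulate a cohort, sample an NCC sub-cohort, and fit both estimators:

```python
import numpy as np
from nccjoint import (SimConfig, simulate_cohort, select_cases_and_censor,
                      draw_controls, JointModelSpec, fit, attach_covariance)

config = SimConfig(N=8000, beta=np.array([0.3, 0.1]), seed=1)
cohort = simulate_cohort(config)                       # latent full cohort
case_ids, censor_time, observed = select_cases_and_censor(cohort, 400)
sample = draw_controls(observed, case_ids, m=1,
                       rng=np.random.default_rng(2))   # 1:1 matched on X2

spec = JointModelSpec(K=2, survival_covariate_names=("X2",),
                      baseline_knots=[0.0, censor_time])

full = attach_covariance(fit(observed, spec, "fjm_ncc"), observed, "fisher")
wtd = attach_covariance(fit(observed, spec, "wjm_ncc",
                            weights=sample.weights), observed,
                        "sandwich", weights=sample.weights)
for res in (full, wtd):
    b1, s1 = res.estimate("beta_1"), res.se("beta_1")
    print(f"{res.variant:8s} beta_1 = {b1:.3f} (SE {s1:.3f}), "
          f"95% CI [{b1 - 1.96 * s1:.3f}, {b1 + 1.96 * s1:.3f}]")
```

Output:

```
fjm_ncc  beta_1 = 0.244 (SE 0.070), 95% CI [0.107, 0.382]
wjm_ncc  beta_1 = 0.271 (SE 0.100), 95% CI [0.075, 0.467]
```

Both estimators cover the generating association `β₁ = 0.3` on this
replicate, and the weighted estimator pays an efficiency price (sandwich
SE 0.100 vs 0.070) for using only the ~10% sub-cohort.

The same steps are available from a shell:

```bash
nccjoint simulate --seed 1 --out-prefix cohort
nccjoint sample --cohort-prefix cohort --m 1 --seed 2 --out-prefix ncc
nccjoint fit --long ncc_long.csv --surv ncc_surv.csv --variant wjm_ncc --out fit.json
nccjoint clr --sample ncc --cause 1 --out clr.json
nccjoint evaluate --scenario 1 --m 1 --reps 200 --out metrics.csv
```

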