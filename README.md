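# retscreen

Risk-based screening for sight-threatening diabetic retinopathy (STDR) by
**longitudinal discriminant analysis**.

People with diabetes are offered annual retinal photography; the grade in each
eye is *R0* (no retinopathy), *R1* (mild non-proliferative / background
retinopathy) or *STDR* (referable, sight-threatening disease). Because the
annual incidence of STDR is low (~2.5%), screening programmes want to move
low-risk patients to two-yearly intervals without missing progressors. This
package implements, end to end, a multivariate longitudinal approach to that
problem — built for biostatisticians evaluating risk-based screening-interval
policies — together with the two simple grade-based stratification rules it is
usually compared against, and a calibrated synthetic cohort generator so the
whole pipeline is testable without access to confidential screening data.

## The model

For patient *i*, screening visit *j* and eye *e* ∈ {R, L}, the binary grade
(0 = R0, 1 = R1) follows a bivariate logistic mixed model

```
y_ije ~ Bernoulli( expit( x_ijᵀ β_e + b_ie ) ),
(b_iR, b_iL) ~ w₁ N(μ₁, Σ₁) + w₂ N(μ₂, Σ₂)
```

with covariates on their reporting scales (diabetes duration per 5 years,
time since first screening per year, SBP per 10 mmHg, HbA1c per 10 mmol/mol,
type-1 and missed-appointment indicators). The two-component Gaussian-mixture
random-intercept pair captures the correlation between the eyes and latent
low-/high-risk subgroups; the component means carry the per-eye intercepts.
Estimation is by Gibbs sampling with Pólya-Gamma augmentation of the logit
link (fully conjugate updates, no tuning).

Two such models are fitted — one on patients who developed STDR within a year
of their final visit, one on patients who did not. A new patient's history is
scored by its marginal likelihood under each model (random effects integrated
out by adaptive Gauss–Hermite quadrature, averaged over posterior draws) and
converted to a 1-year STDR risk by Bayes' rule with the group prevalence:

```
P(STDR | history) = π L_STDR / (π L_STDR + (1-π) L_nonSTDR)
```

The operating threshold is the ROC point nearest the top-left corner.
Comparators: the *two-episode rule* (low risk iff two successive attended
annual episodes with all four eye-grades R0) and the *current-episode rule*
(low risk iff both eyes R0 at the prediction visit).

## Worked example

```bash
retscreen simulate --n 2000 --seed 5 --out cohort/
retscreen run --cohort cohort/ --out results/ --seed 5
```

or in Python:

```python
from retscreen import (GeneratorConfig, simulate_cohort, apply_exclusions,
                       build_prediction_instances, ModelSpec, MCMCConfig,
                       fit_mcmc, posterior_odds_ratios)
from retscreen.simulate import GROUP_NONSTDR

cfg = GeneratorConfig(n_patients=1500, followup_min=6.0, followup_max=6.0, seed=11)
patients, _ = simulate_cohort(cfg, group=GROUP_NONSTDR)
instances = build_prediction_instances(apply_exclusions(patients)[0])
fit = fit_mcmc(instances, cfg.truth_nonstdr.spec,
               MCMCConfig(n_iter=2500, burn_in=700, thin=3, n_chains=1), seed=1)
print(posterior_odds_ratios(fit).query("eye == 'right'")
      [["covariate", "or", "ci_lo", "ci_hi"]].round(3).to_string(index=False))
```

prints

```
covariate    or  ci_lo  ci_hi
 duration 2.147  1.925  2.413
    type1 1.832  1.124  2.914
     time 0.990  0.950  1.028
      sbp 1.023  0.958  1.091
    hba1c 1.042  0.977  1.112
```

i.e. the fit recovers the generator's ground-truth odds ratios (2.25, 2.44,
0.97, 1.07, 1.04): the odds of showing mild retinopathy rather than none
multiply by ~2.1 per 5 years of diabetes duration, and every covariate's 95%
credible interval brackets its true effect. `retscreen run`
additionally writes a comparison report (sensitivity / specificity / PCC /
PPV / screening reduction) for the discriminant model and both stratification
rules on a held-out 30% test split.

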