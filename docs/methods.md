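# Methods

## Problem and data model

The package predicts whether a person with diabetes will develop
sight-threatening diabetic retinopathy (STDR) within one year of a given
screening visit, from their longitudinal screening and primary-care history.
A cohort is three tables: screening episodes (one row per scheduled
appointment, per-eye grade R0/R1/STDR when attended), time-varying clinical
covariates (HbA1c mmol/mol, SBP/DBP mmHg, total cholesterol mmol/L on their
own visit grid), and demographics (sex, age at first visit, diabetes type,
diabetes duration at first visit). Time is continuous, in years since each
patient's first screening episode.

Preprocessing mirrors screening-programme practice:

* **Exclusions**, applied in order and counting each patient once: fewer than
  two attended episodes; no clinical (covariate) record within 18 months of
  the final visit; STDR already present at the first attended episode. The
  18-month window is applied to covariate records rather than screening
  episodes — the rule concerns *clinical* visits, and covariate records are
  our representation of those.
* **Final visit and group**: the earliest episode with STDR in either eye
  (STDR group; later data ignored) or the last attended episode (non-STDR
  group).
* **Covariate alignment**: each episode takes each covariate's record nearest
  in time, independently per variable; exact-distance ties go to the earlier
  record (stable and reproducible). Episodes with a completely unrecorded
  required covariate are dropped from model histories, not imputed
  (complete-case handling).
* **Prediction instances**: the history is truncated at the last attended
  episode at or before `final_time − 1 year + 0.25`. The quarter-year grace
  keeps the episode scheduled roughly one year before the final visit in the
  history despite scheduling jitter (appointments have ~6-week recall
  windows); without it about half of all penultimate visits would be lost to
  jitter alone. The 1-year outcome label is the patient's group, known by
  construction for everyone.

## The bivariate mixture GLMM

Per patient *i*, visit *j*, eye *e*: `y_ije ~ Bernoulli(expit(x_ijᵀβ_e + b_ie))`
with `(b_iR, b_iL)` drawn from a two-component bivariate Gaussian mixture.
Covariates enter pre-scaled to their reporting units (duration/5 y, SBP/10
mmHg, HbA1c/10 mmol/mol, time/1 y, binary indicators unscaled), so each
coefficient is directly a log odds ratio per reporting unit. There is no
fixed intercept: it would be unidentified against the mixture means, which
therefore carry the per-eye intercepts. Fixed effects are estimated per eye
by default (`share_eyes=True` pools them when right/left effects are assumed
equal, as in the synthetic generator's ground truth).

**Sampler.** Gibbs with Pólya-Gamma augmentation: each observation receives a
PG(1, η) latent variable, making every conditional conjugate — Gaussian for
β and for each patient's intercept pair (closed-form 2×2 updates), categorical
for component membership, Dirichlet(1,1) for weights, and semi-conjugate
normal / inverse-Wishart for component means and covariances. Priors (the
problem dictates none): β ~ N(0, 10²), means ~ N(0, 10²I), covariances ~
IW(4, I); all overridable. The PG(1, z) draws use the exact
Devroye-style alternating-series rejection sampler (numba-compiled; validated
in tests against the infinite-series moments of the PG law).

**Centering.** Covariates are centred at their sample means during sampling
and the sampled mixture means are shifted back (`μ → μ − x̄ᵀβ` per draw).
This is an exact reparameterization; without it the near-constant covariates
(SBP, HbA1c) mix an order of magnitude more slowly because their coefficients
trade off against the intercept location.

**Chains and diagnostics.** Defaults 10 000 iterations, 2 000 burn-in,
thinning 5, 2 chains; convergence is monitored by split-R̂ per fixed effect
(each chain split in halves), warning above 1.1. Label switching is resolved
post hoc by ordering components on the sum of their mean intercepts
(component 1 = lower risk). Complete separation (an outcome level absent)
aborts with an explicit error.

**Model comparison.** The penalized expected-deviance criterion is
implemented as posterior-expected deviance plus an effective-parameter
penalty, `2·D̄ − D(θ̄)`, where deviance is −2× the *marginal* log likelihood
(random effects integrated over the mixture) and `θ̄` is the posterior mean.
This is one standard member of the penalized-deviance family; the exact
penalty used in the original analysis is not published, so this choice is
documented as an approximation. It is evaluated on an evenly spaced subset of
draws, hence deterministic given a fit. Forward selection adds the candidate
with the best criterion improvement until none improves, with a `forced` set
always retained (e.g. HbA1c kept on clinical grounds regardless of
significance).

## Discriminant scoring

A patient's marginal likelihood under a parameter point integrates the
intercept pair out of the Bernoulli product: a 2-D integral per mixture
component, evaluated by adaptive Gauss–Hermite quadrature (20 nodes per
dimension) centred on the conditional mode of the log-concave integrand
(a few Newton steps; the Hessian supplies the scaling). Point-mass components
are evaluated in closed form; a non-finite quadrature result falls back to
Monte-Carlo integration with a warning. Tests require 20-node results to
match 45-node results to 1e-8 and a 10⁶-draw Monte-Carlo oracle to 1e-3.

Posterior uncertainty is propagated by averaging the likelihood over 50
evenly spaced retained draws per group (the *marginal* prediction variant;
which variant the original analysis used is unstated, so a plug-in
posterior-median variant is provided behind a flag). Group probabilities are
`π L_STDR / (π L_STDR + (1−π) L_nonSTDR)` computed on the log scale
(log-sum-exp throughout; likelihood ratios of e^±1000 produce 0/1 rather than
NaN). Prevalence π defaults to the training-set group fraction and can be set
to an external incidence. Classification is strict: predicted STDR iff
probability > threshold.

## Evaluation protocol

Empirical ROC over all distinct score thresholds (strict classification), AUC
by trapezoid — identical to Mann-Whitney concordance with half credit for
ties, and asserted equal to exhaustive pair enumeration in tests. The
operating threshold minimizes the Euclidean distance to (sens, spec) = (1, 1);
ties go to the lower threshold (higher sensitivity). Repeated validation uses
stratified 70/30 splits of each prognostic group; both models are refitted
per split, the threshold is chosen on the *training* ROC only (the source
analysis is silent here; choosing on test data would bias the operating point
optimistically), and metrics are averaged over repeats with 2.5/97.5
percentile intervals (the CI method is likewise unstated in the source;
percentile-over-repeats is the package's documented choice). Policy
arithmetic: PCC is the group-size-weighted average of sensitivity and
specificity; PPV follows Bayes' rule from (sens, spec, prevalence); moving a
fraction *f* of patients to biennial screening saves *f*/2 of all episodes
(steady-state annual scheduling, no re-stratification dynamics).

Stratification rules: the two-episode rule reads the last two scheduled
episodes before the prediction time; a gap above 1.25 years between them
counts as a missed episode (annual schedule plus the recall window), and any
missed episode forces high risk, as does an observation span of a single
episode (flagged `SINGLE_EPISODE`). The current-episode rule reads the
prediction-time episode alone, treating a missed one as high risk.

## Synthetic cohort generator

The generator emulates the screening cohort the method was developed on:
13 103 patients by default, 2.6% STDR prevalence, annual visits (gap
1.0 ± 0.1 y) over a follow-up uniform on [2, 10] years (median 6), per-visit
missed-appointment probabilities 4.3% (non-STDR) vs 23.5% (STDR), and
group-conditional demographics (age 59.7 ± 13.3 vs 52.9 ± 14.4; type-1
fraction 4.6% vs 19.4%; duration and HbA1c as shifted log-normals
quantile-matched to published median/IQRs; SBP/DBP/cholesterol as normal
patient means with AR(1) within-patient series, ρ = 0.7).

Each patient's group is drawn first; the group's own mixture GLMM — with the
published odds ratios as fixed-effect truth — then generates the grade
trajectory. Mixture means and covariances are not published; the defaults
keep the published component weights (0.362 low-risk in the non-STDR group,
0.292 high-risk in the STDR group) and were calibrated once so the grade
distributions at the prediction visit approximate the published table
(R0/R0-R0/R1-R1/R1 ≈ 74/19/7% non-STDR vs 7/23/70% STDR against the table's
79/13/8 and 12/14/74). Exact matching is neither required nor claimed: the
inter-eye concordance achievable under visit-wise conditionally independent
Bernoulli draws is bounded, and the real process has grade persistence the
model does not represent.

What the generator does **not** emulate: a mechanism for STDR onset (the
STDR grade is imposed at the STDR-group patient's final visit, uniform over
the follow-up range — no published onset model exists), treatment effects,
competing mortality, covariate missingness (off by default), and real-data
grade persistence. Passing tests therefore demonstrate internal consistency
of estimation and scoring under the assumed model, not clinical performance
on real screening data.

Randomness: one global seed; per-patient substreams are spawned
deterministically, so enlarging a cohort leaves existing patients unchanged,
and identical seeds give byte-identical output files.

## Problem sizes used in checks

Simulation sizes were chosen to keep each check's Monte-Carlo error small
relative to its acceptance band: parameter-recovery runs in
`scripts/acceptance.py` use 3 000 patients × ~6 annual visits for the
non-STDR model (reported as the median over three replicate cohorts, since
the between-cohort spread of the posterior median is the dominant error term)
and 1 500 × ~6 for the STDR model, each with 10 000-iteration chains; the
test suite uses 1 500/800 patients with 2 500-iteration chains, and the
end-to-end check uses a 260-patient two-group cohort with three 70/30
repeats. Fits in tests run single chains; multi-chain split-R̂ remains the
library default.

## Known limitations

* Two mixture components only; no random slopes; logit link only.
* The deviance penalty is an approximation to the published criterion (see
  above).
* Scoring is at one prediction time per patient; dynamic re-scoring as new
  visits accrue is out of scope.
* The weight-ordering relabelling assumes the two components stay separated
  in mean; heavily overlapping components can still swap within a chain
  (harmless for the discriminant, which is relabelling-invariant).
* Misclassification costs are not modelled; sensitivity and specificity are
  weighted only through prevalence.
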