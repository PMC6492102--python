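"""Shared fixtures: small synthetic cohorts and pre-fitted group models.

Everything is generated programmatically at session start with fixed seeds;
chain lengths are kept short — enough for stable posterior summaries in the
tests that use them, not for publication-grade inference.
"""

import numpy as np
import pytest

from retscreen.cohort import apply_exclusions, build_prediction_instances
from retscreen.discriminant import GroupModelPair
from retscreen.glmm import MCMCConfig, fit_mcmc
from retscreen.simulate import GeneratorConfig, simulate_cohort

#: covariate set shared by both group models in end-to-end fixtures
PIPELINE_COVARIATES = ("duration", "time", "hba1c", "missed_prev")

SHORT_MCMC = MCMCConfig(n_iter=1000, burn_in=300, thin=2, n_chains=1)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Enriched two-group cohort (fast to fit): 400 patients, 30% STDR."""
    cfg = GeneratorConfig(n_patients=400, prevalence_stdr=0.30,
                          followup_min=5.0, followup_max=8.0, seed=20260901)
    patients, truth = simulate_cohort(cfg)
    return cfg, patients, truth


@pytest.fixture(scope="session")
def mixed_instances(mixed_cohort):
    _, patients, _ = mixed_cohort
    kept, _ = apply_exclusions(patients)
    return build_prediction_instances(kept)


@pytest.fixture(scope="session")
def fitted_pair(mixed_instances):
    """Group models fitted on the first 70% of each group of the mixed cohort."""
    from retscreen.glmm import ModelSpec
    spec = ModelSpec(covariates=PIPELINE_COVARIATES)
    labels = np.array([i.label for i in mixed_instances])
    stdr = [i for i in mixed_instances if i.label]
    non = [i for i in mixed_instances if not i.label]
    tr_s = stdr[: int(0.7 * len(stdr))]
    tr_n = non[: int(0.7 * len(non))]
    te = stdr[int(0.7 * len(stdr)):] + non[int(0.7 * len(non)):]
    fit_s = fit_mcmc(tr_s, spec, SHORT_MCMC, seed=11)
    fit_n = fit_mcmc(tr_n, spec, SHORT_MCMC, seed=12)
    pair = GroupModelPair(fit_stdr=fit_s, fit_nonstdr=fit_n,
                          prevalence_stdr=len(tr_s) / (len(tr_s) + len(tr_n)))
    return pair, te
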