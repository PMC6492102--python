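"""Mixture GLMM: link arithmetic, Gibbs sampler correctness, model comparison."""

import numpy as np
import pandas as pd
import pytest

from retscreen.cohort import PredictionInstance
from retscreen.discriminant import marginal_log_likelihood
from retscreen.glmm import (MCMCConfig, MixtureGLMMParams, ModelSpec, PosteriorFit,
                            fit_mcmc, forward_select, penalized_expected_deviance,
                            posterior_odds_ratios, transition_probability)
from retscreen.simulate import GROUP_NONSTDR, GeneratorConfig, simulate_cohort
from retscreen.cohort import apply_exclusions, build_prediction_instances

QUICK = MCMCConfig(n_iter=600, burn_in=200, thin=2, n_chains=1)


def _bernoulli_instances(rng, n_patients, n_visits, p=0.5):
    """Covariate-free histories with iid Bernoulli(p) grades."""
    out = []
    for i in range(n_patients):
        grades = (rng.random((n_visits, 2)) < p).astype(int)
        covs = pd.DataFrame({"time": np.arange(n_visits, dtype=float)})
        out.append(PredictionInstance(
            patient_id=f"B{i}", prediction_time=float(n_visits),
            times=np.arange(n_visits, dtype=float), grades=grades,
            covariates=covs, episodes=[], missed_previous=False, label=False))
    return out


class TestTransitionProbability:
    def test_logit_symmetry_and_monotonicity(self):
        x = np.array([[1.0, 2.0]])
        beta = np.array([0.5, -0.25])
        assert transition_probability(x, beta, 0.0)[0] == pytest.approx(0.5)
        probs = [transition_probability(x, beta, b)[0] for b in (-30, -5, 0, 5, 30)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[0] < 1e-12 and probs[-1] > 1 - 1e-12

    def test_five_year_duration_multiplies_odds(self):
        beta = np.array([np.log(2.25)])   # per 5 scaled years
        p0 = transition_probability([[1.0]], beta, -2.0)[0]
        p1 = transition_probability([[2.0]], beta, -2.0)[0]
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(2.25, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            transition_probability(np.ones((1, 3)), np.ones(2), 0.0)


class TestORTable:
    def _fake_fit(self, beta_draws):
        S, p, _ = beta_draws.shape
        spec = ModelSpec(covariates=("duration", "time")[:p])
        return PosteriorFit(spec=spec, beta=beta_draws,
                            weights=np.tile([0.5, 0.5], (S, 1)),
                            means=np.zeros((S, 2, 2)),
                            covariances=np.tile(np.eye(2), (S, 2, 1, 1)),
                            config=MCMCConfig(), seed=0, n_patients=100)

    def test_zero_coefficient_gives_unit_or(self):
        fit = self._fake_fit(np.zeros((200, 1, 2)))
        tab = posterior_odds_ratios(fit)
        assert (tab["or"] == 1.0).all()
        assert (tab["ci_lo"] == 1.0).all() and (tab["ci_hi"] == 1.0).all()

    def test_scaled_coefficient_reproduces_published_or(self):
        # 0.16219 per year of duration, reported per 5 years
        fit = self._fake_fit(np.full((200, 1, 2), 5 * 0.16219))
        tab = posterior_odds_ratios(fit)
        assert tab["or"].iloc[0] == pytest.approx(2.25, abs=0.005)
        # layout mirrors point-and-interval reporting per risk factor and eye
        assert list(tab.columns) == ["covariate", "unit", "eye", "or", "ci_lo", "ci_hi"]
        assert ((tab["ci_lo"] <= tab["or"]) & (tab["or"] <= tab["ci_hi"])).all()

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            posterior_odds_ratios(self._fake_fit(np.zeros((50, 1, 2))))


class TestGibbsSampler:
    def test_balanced_bernoulli_marginal_intercept_near_zero(self):
        rng = np.random.default_rng(2)
        inst = _bernoulli_instances(rng, 250, 6, p=0.5)
        fit = fit_mcmc(inst, ModelSpec(covariates=()), QUICK, seed=1)
        # the implied marginal intercept is the weight-averaged mixture mean
        marginal = np.einsum("sk,ske->se", fit.weights, fit.means)
        assert np.abs(np.median(marginal, axis=0)).max() < 0.1

    def test_retained_draws_satisfy_invariants(self):
        rng = np.random.default_rng(3)
        inst = _bernoulli_instances(rng, 40, 4, p=0.4)
        fit = fit_mcmc(inst, ModelSpec(covariates=("time",)), QUICK, seed=2)
        assert np.abs(fit.weights.sum(axis=1) - 1.0).max() < 1e-12
        for s in range(0, fit.n_draws, 7):
            fit.params_at(s).validate()
        # relabelling orders components by summed mean intercepts
        assert (fit.means.sum(axis=2)[:, 0] <= fit.means.sum(axis=2)[:, 1]).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        inst = _bernoulli_instances(rng, 35, 4)
        spec = ModelSpec(covariates=("time",))
        f1 = fit_mcmc(inst, spec, QUICK, seed=5)
        f2 = fit_mcmc(inst, spec, QUICK, seed=5)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.covariances, f2.covariances)

    def test_complete_separation_rejected(self):
        rng = np.random.default_rng(5)
        inst = _bernoulli_instances(rng, 40, 4, p=0.0)
        with pytest.raises(ValueError, match="separation"):
            fit_mcmc(inst, ModelSpec(covariates=()), QUICK, seed=0)

    def test_too_few_patients_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="30"):
            fit_mcmc(_bernoulli_instances(rng, 10, 3), ModelSpec(covariates=()), QUICK)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        inst = _bernoulli_instances(rng, 35, 4)
        fit = fit_mcmc(inst, ModelSpec(covariates=("time",)), QUICK, seed=8)
        fit.save(tmp_path / "fit.npz")
        back = PosteriorFit.load(tmp_path / "fit.npz")
        assert back.spec == fit.spec
        assert np.array_equal(back.beta, fit.beta)
        assert back.rhat == fit.rhat


class TestAgainstLogisticRegressionOracle:
    def test_fixed_effects_match_statsmodels_mle_without_random_variance(self):
        """Data generated with a point-mass intercept (no between-patient
        heterogeneity) is plain logistic regression: the Gibbs posterior
        median slope must agree with the statsmodels MLE."""
        import statsmodels.api as sm
        rng = np.random.default_rng(21)
        n_pat, n_vis = 400, 5
        slope, intercept = 0.7, -1.0
        out = []
        rows_x, rows_y = [], []
        for i in range(n_pat):
            x = rng.normal(0, 1, n_vis)
            p = 1 / (1 + np.exp(-(intercept + slope * x)))
            grades = (rng.random((n_vis, 2)) < p[:, None]).astype(int)
            covs = pd.DataFrame({"time": x})
            out.append(PredictionInstance(
                patient_id=f"O{i}", prediction_time=float(n_vis),
                times=np.arange(n_vis, dtype=float), grades=grades,
                covariates=covs, episodes=[], missed_previous=False, label=False))
            rows_x.append(np.repeat(x, 2))
            rows_y.append(grades.ravel())
        X = sm.add_constant(np.concatenate(rows_x))
        mle = sm.Logit(np.concatenate(rows_y), X).fit(disp=0)

        fit = fit_mcmc(out, ModelSpec(covariates=("time",), share_eyes=True),
                       MCMCConfig(n_iter=1200, burn_in=400, thin=2, n_chains=1),
                       seed=3)
        post_slope = float(np.median(fit.beta[:, 0, 0]))
        post_intercept = float(np.median(
            np.einsum("sk,ske->se", fit.weights, fit.means)[:, 0]))
        assert post_slope == pytest.approx(mle.params[1], abs=3 * mle.bse[1])
        assert post_intercept == pytest.approx(mle.params[0], abs=0.15)


class TestLikelihoodStructure:
    def _params(self, weights=(0.4, 0.6)):
        return MixtureGLMMParams(
            beta=np.array([[0.3], [0.3]]).T,
            weights=np.array(weights),
            means=np.array([[-1.5, -1.2], [0.6, 0.4]]),
            covariances=np.array([np.eye(2) * 0.5, [[0.8, 0.4], [0.4, 0.8]]]))

    def _instance(self, rng, n=4):
        grades = (rng.random((n, 2)) < 0.4).astype(int)
        return PredictionInstance(
            patient_id="L", prediction_time=float(n), times=np.arange(n, dtype=float),
            grades=grades, covariates=pd.DataFrame({"time": np.arange(n, dtype=float)}),
            episodes=[], missed_previous=False, label=False)

    def test_likelihood_invariant_under_component_relabelling(self):
        rng = np.random.default_rng(10)
        inst = self._instance(rng)
        spec = ModelSpec(covariates=("time",))
        p = self._params()
        swapped = MixtureGLMMParams(
            beta=p.beta, weights=p.weights[::-1].copy(),
            means=p.means[::-1].copy(), covariances=p.covariances[::-1].copy())
        a = marginal_log_likelihood(inst, p, spec)
        b = marginal_log_likelihood(inst, swapped, spec)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_single_component_equals_bernoulli_product(self):
        """With the mixture collapsed to one point mass the marginal
        likelihood is the closed-form independent-Bernoulli product."""
        rng = np.random.default_rng(11)
        inst = self._instance(rng, n=5)
        spec = ModelSpec(covariates=("time",))
        p = self._params(weights=(1.0, 0.0))
        p.covariances[:] = 0.0
        from retscreen.glmm import inverse_logit
        X = spec.design_matrix(inst)
        eta = X @ p.beta + p.means[0]
        pr = inverse_logit(eta)
        closed = float(np.sum(inst.grades * np.log(pr)
                              + (1 - inst.grades) * np.log(1 - pr)))
        assert marginal_log_likelihood(inst, p, spec) == pytest.approx(closed,
                                                                       abs=1e-10)


class TestModelComparison:
    @pytest.fixture(scope="class")
    def strong_covariate_instances(self):
        """Small cohorts whose grade dynamics are driven by time alone."""
        cohorts = []
        for rep in range(3):
            cfg = GeneratorConfig(n_patients=80, followup_min=5.0, followup_max=5.0,
                                  seed=300 + rep)
            cfg.truth_nonstdr.params.beta[:] = 0.0
            idx = cfg.truth_nonstdr.spec.covariates.index("time")
            cfg.truth_nonstdr.params.beta[idx] = np.log(2.5)
            patients, _ = simulate_cohort(cfg, group=GROUP_NONSTDR)
            cohorts.append(build_prediction_instances(apply_exclusions(patients)[0]))
        return cohorts

    def test_ped_deterministic_given_draws(self, strong_covariate_instances):
        inst = strong_covariate_instances[0]
        fit = fit_mcmc(inst, ModelSpec(covariates=("time",)), QUICK, seed=1)
        a = penalized_expected_deviance(fit, inst, n_draws=20)
        b = penalized_expected_deviance(fit, inst, n_draws=20)
        assert a == b

    def test_true_model_beats_null(self, strong_covariate_instances):
        wins = 0
        for rep, inst in enumerate(strong_covariate_instances):
            true_fit = fit_mcmc(inst, ModelSpec(covariates=("time",)), QUICK, seed=rep)
            null_fit = fit_mcmc(inst, ModelSpec(covariates=()), QUICK, seed=rep)
            ped_true = penalized_expected_deviance(true_fit, inst, n_draws=20)
            ped_null = penalized_expected_deviance(null_fit, inst, n_draws=20)
            wins += ped_true < ped_null
        assert wins >= 2

    def test_forward_selection_finds_signal_and_keeps_forced(self,
                                                             strong_covariate_instances):
        inst = strong_covariate_instances[0]
        spec = forward_select(candidates=["time", "sex_male"], forced=["hba1c"],
                              instances=inst, mcmc=QUICK, seed=3, ped_draws=15)
        assert "hba1c" in spec.covariates     # forced stays regardless of criterion
        assert "time" in spec.covariates

    def test_greedy_logic_stops_when_nothing_improves(self):
        """Stopping rule and greedy order, checked against a stub criterion."""
        table = {(): 100.0, ("age",): 100.0, ("sbp",): 95.0, ("dbp",): 98.0,
                 ("age", "sbp"): 96.0, ("dbp", "sbp"): 97.0}
        spec = forward_select(candidates=["age", "sbp", "dbp"], forced=[],
                              instances=[],
                              criterion_fn=lambda c: table[tuple(sorted(c))])
        assert spec.covariates == ("sbp",)
        # empty improvement at step 1: forced covariates only
        worse = forward_select(candidates=["age"], forced=["dbp"], instances=[],
                               criterion_fn=lambda c: 50.0 + len(c))
        assert worse.covariates == ("dbp",)
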