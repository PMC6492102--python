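"""Bivariate binary mixed model with mixture random intercepts, fitted by MCMC.

The longitudinal outcome is the per-eye binary retinopathy grade (0 = no DR,
1 = mild NPDR/BDR).  For patient ``i``, visit ``j`` and eye ``e`` (right,
left)::

    y_ije ~ Bernoulli( logit^-1( x_ij . beta_e + b_ie ) )

with a patient-specific intercept pair ``b_i = (b_iR, b_iL)`` drawn from a
two-component bivariate Gaussian mixture::

    b_i ~ w_1 N(mu_1, Sigma_1) + w_2 N(mu_2, Sigma_2)

The mixture captures latent low-/high-risk subgroups and the correlation
between the two eyes; the component means carry the per-eye intercepts (no
separate fixed intercept, which would not be identified against them).

Estimation is by Gibbs sampling with Pólya-Gamma augmentation of the logit
link, giving fully conjugate conditional updates throughout: Gaussian for the
fixed effects and random intercepts, categorical for component membership,
Dirichlet for the weights, and normal / inverse-Wishart for the component
means and covariances.  Mixture label switching is resolved after sampling by
reordering components on the sum of their mean intercepts.

Covariates enter on the scales used for reporting odds ratios: diabetes
duration per 5 years, SBP per 10 mmHg, HbA1c per 10 mmol/mol, time since
first screening per year, plus binary indicators (type 1 diabetes, previous
appointment missed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import invwishart

from ._pg import draw_pg, seed_pg
from .cohort import PredictionInstance

logger = logging.getLogger("retscreen")

EYES = ("right", "left")

#: covariate registry: name -> (column in PredictionInstance.covariates,
#: divisor applied before entering the linear predictor, display unit)
COVARIATE_SCALINGS: dict[str, tuple[str, float, str]] = {
    "duration": ("duration", 5.0, "per 5 years' disease duration"),
    "type1": ("type1", 1.0, "type 1 diabetes"),
    "time": ("time", 1.0, "per year since first screening"),
    "sbp": ("sbp", 10.0, "per 10 mmHg SBP"),
    "hba1c": ("hba1c", 10.0, "per 10 mmol/mol HbA1c"),
    "missed_prev": ("missed_prev", 1.0, "previous appointment missed"),
    "dbp": ("dbp", 10.0, "per 10 mmHg DBP"),
    "chol": ("chol", 1.0, "per mmol/L cholesterol"),
    "sex_male": ("sex_male", 1.0, "male sex"),
    "age": ("age", 10.0, "per 10 years of age"),
}


def inverse_logit(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    return 0.5 * (1.0 + np.tanh(np.asarray(x, dtype=float) / 2.0))


@dataclass(frozen=True)
class ModelSpec:
    """Covariate set and structural options of the bivariate model."""

    covariates: tuple[str, ...]
    share_eyes: bool = False
    n_components: int = 2

    def __post_init__(self):
        unknown = [c for c in self.covariates if c not in COVARIATE_SCALINGS]
        if unknown:
            raise ValueError(f"unknown covariates: {unknown}")
        if self.n_components != 2:
            raise ValueError("only two mixture components are supported")

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def design_matrix(self, instance: PredictionInstance) -> np.ndarray:
        """Scaled covariate matrix (one row per usable episode)."""
        cols = []
        for name in self.covariates:
            col, scale, _ = COVARIATE_SCALINGS[name]
            cols.append(instance.covariates[col].to_numpy(dtype=float) / scale)
        if not cols:
            return np.empty((instance.n_visits, 0))
        return np.column_stack(cols)


@dataclass
class MixtureGLMMParams:
    """One parameter point of the model (a posterior draw or generator truth).

    ``beta`` is (p, 2) with columns (right, left) on the scaled-covariate
    log-odds scale; ``means`` is (2 components, 2 eyes); ``covariances`` is
    (2, 2, 2).  The per-eye intercepts live in the mixture means.
    """

    beta: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def validate(self, atol: float = 1e-8) -> None:
        beta = np.atleast_2d(self.beta)
        if beta.shape[1] != 2:
            raise ValueError("beta must have one column per eye")
        if self.weights.shape != (2,) or abs(self.weights.sum() - 1.0) > atol \
                or (self.weights < -atol).any():
            raise ValueError("weights must be a length-2 simplex")
        if self.means.shape != (2, 2):
            raise ValueError("means must be (2 components, 2 eyes)")
        for k in range(2):
            cov = self.covariances[k]
            if not np.allclose(cov, cov.T, atol=atol) or np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance of component {k} is not symmetric PD")


def transition_probability(x: np.ndarray, beta: np.ndarray, b: float) -> np.ndarray:
    """P(grade R1) = logit^-1(x . beta + b) for scaled covariate rows ``x``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    if x.shape[1] != beta.size:
        raise ValueError(f"covariate dimension {x.shape[1]} != beta dimension {beta.size}")
    return inverse_logit(x @ beta + b)


@dataclass
class MCMCConfig:
    """Chain settings and priors (all conditionally conjugate)."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    n_chains: int = 2
    beta_prior_sd: float = 10.0
    mean_prior_sd: float = 10.0
    dirichlet_alpha: float = 1.0
    wishart_df: float = 4.0
    rhat_threshold: float = 1.1

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorFit:
    """Retained MCMC draws plus chain metadata and convergence diagnostics."""

    spec: ModelSpec
    beta: np.ndarray        # (S, p, 2)
    weights: np.ndarray     # (S, 2)
    means: np.ndarray       # (S, 2, 2)
    covariances: np.ndarray  # (S, 2, 2, 2)
    config: MCMCConfig
    seed: int
    n_patients: int
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def params_at(self, s: int) -> MixtureGLMMParams:
        return MixtureGLMMParams(beta=self.beta[s], weights=self.weights[s],
                                 means=self.means[s], covariances=self.covariances[s])

    def thin_indices(self, n: int) -> np.ndarray:
        """Evenly spaced draw indices (deterministic)."""
        n = min(n, self.n_draws)
        return np.unique(np.linspace(0, self.n_draws - 1, n).round().astype(int))

    def posterior_mean_params(self) -> MixtureGLMMParams:
        return MixtureGLMMParams(
            beta=self.beta.mean(axis=0), weights=self.weights.mean(axis=0),
            means=self.means.mean(axis=0), covariances=self.covariances.mean(axis=0))

    def posterior_median_params(self) -> MixtureGLMMParams:
        """Element-wise posterior medians (covariances repaired to PD if needed)."""
        cov = np.median(self.covariances, axis=0)
        for k in range(2):
            lim = 0.99 * np.sqrt(cov[k, 0, 0] * cov[k, 1, 1])
            cov[k, 0, 1] = cov[k, 1, 0] = np.clip(cov[k, 0, 1], -lim, lim)
        return MixtureGLMMParams(
            beta=np.median(self.beta, axis=0), weights=np.median(self.weights, axis=0),
            means=np.median(self.means, axis=0), covariances=cov)

    def save(self, path) -> None:
        np.savez_compressed(
            path, beta=self.beta, weights=self.weights, means=self.means,
            covariances=self.covariances, covariate_names=np.array(self.spec.covariates),
            share_eyes=self.spec.share_eyes, seed=self.seed, n_patients=self.n_patients,
            n_iter=self.config.n_iter, burn_in=self.config.burn_in,
            thin=self.config.thin, n_chains=self.config.n_chains,
            rhat_names=np.array(list(self.rhat)),
            rhat_values=np.array(list(self.rhat.values())))

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        z = np.load(path, allow_pickle=False)
        spec = ModelSpec(covariates=tuple(str(c) for c in z["covariate_names"]),
                         share_eyes=bool(z["share_eyes"]))
        cfg = MCMCConfig(n_iter=int(z["n_iter"]), burn_in=int(z["burn_in"]),
                         thin=int(z["thin"]), n_chains=int(z["n_chains"]))
        return cls(spec=spec, beta=z["beta"], weights=z["weights"], means=z["means"],
                   covariances=z["covariances"], config=cfg, seed=int(z["seed"]),
                   n_patients=int(z["n_patients"]),
                   rhat=dict(zip([str(n) for n in z["rhat_names"]],
                                 [float(v) for v in z["rhat_values"]])))


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------

def _pack(instances: Sequence[PredictionInstance], spec: ModelSpec):
    xs, ys, pats = [], [], []
    for i, inst in enumerate(instances):
        xs.append(spec.design_matrix(inst))
        ys.append(inst.grades)
        pats.append(np.full(inst.n_visits, i, dtype=np.int64))
    X = np.vstack(xs)
    y = np.vstack(ys).astype(float)
    pat = np.concatenate(pats)
    return X, y, pat


def _inv2(m: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a stack of 2x2 matrices."""
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    out = np.empty_like(m)
    out[..., 0, 0] = m[..., 1, 1] / det
    out[..., 1, 1] = m[..., 0, 0] / det
    out[..., 0, 1] = -m[..., 0, 1] / det
    out[..., 1, 0] = -m[..., 1, 0] / det
    return out


def _sample_mvn2(rng, prec: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Draw from N(prec^-1 rhs, prec^-1) for a stack of 2x2 precisions."""
    cov = _inv2(prec)
    mean = np.einsum("...ij,...j->...i", cov, rhs)
    l11 = np.sqrt(cov[..., 0, 0])
    l21 = cov[..., 1, 0] / l11
    l22 = np.sqrt(np.maximum(cov[..., 1, 1] - l21 ** 2, 1e-300))
    z = rng.standard_normal(mean.shape)
    out = np.empty_like(mean)
    out[..., 0] = mean[..., 0] + l11 * z[..., 0]
    out[..., 1] = mean[..., 1] + l21 * z[..., 0] + l22 * z[..., 1]
    return out


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def _run_chain(X, y, pat, n_patients, spec: ModelSpec, cfg: MCMCConfig,
               np_seed: int, pg_seed: int):
    rng = np.random.default_rng(np_seed)
    seed_pg(pg_seed)
    N, p = X.shape
    n = n_patients
    kappa = y - 0.5
    prior_prec_beta = 1.0 / cfg.beta_prior_sd ** 2
    prior_prec_mu = 1.0 / cfg.mean_prior_sd ** 2

    beta = np.zeros((p, 2))
    b = np.zeros((n, 2))
    comp = rng.integers(0, 2, n)
    w = np.array([0.5, 0.5])
    mu = np.array([[-1.0, -1.0], [1.0, 1.0]])
    sig = np.array([np.eye(2), np.eye(2)])

    S = cfg.n_draws_per_chain
    out_beta = np.empty((S, p, 2))
    out_w = np.empty((S, 2))
    out_mu = np.empty((S, 2, 2))
    out_sig = np.empty((S, 2, 2, 2))
    s_idx = 0

    eye2 = np.eye(2)
    for it in range(cfg.n_iter):
        xb = X @ beta                           # (N, 2)
        eta = xb + b[pat]
        om = draw_pg(np.abs(eta).ravel()).reshape(N, 2)

        # fixed effects
        if p:
            if spec.share_eyes:
                A = prior_prec_beta * np.eye(p)
                rhs = np.zeros(p)
                for e in range(2):
                    A += (X * om[:, e:e + 1]).T @ X
                    rhs += X.T @ (kappa[:, e] - om[:, e] * b[pat, e])
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(A, rhs)
                draw = mean + np.linalg.solve(L.T, rng.standard_normal(p))
                beta[:, 0] = beta[:, 1] = draw
            else:
                for e in range(2):
                    A = prior_prec_beta * np.eye(p) + (X * om[:, e:e + 1]).T @ X
                    rhs = X.T @ (kappa[:, e] - om[:, e] * b[pat, e])
                    L = np.linalg.cholesky(A)
                    mean = np.linalg.solve(A, rhs)
                    beta[:, e] = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            xb = X @ beta

        # random intercepts
        sig_inv = _inv2(sig)                    # (2, 2, 2)
        Qk = sig_inv[comp]                      # (n, 2, 2)
        prec = Qk.copy()
        resid = kappa - om * xb                 # (N, 2)
        for e in range(2):
            prec[:, e, e] += np.bincount(pat, weights=om[:, e], minlength=n)
        rhs = np.einsum("nij,nj->ni", Qk, mu[comp])
        for e in range(2):
            rhs[:, e] += np.bincount(pat, weights=resid[:, e], minlength=n)
        b = _sample_mvn2(rng, prec, rhs)

        # component membership
        logp = np.empty((n, 2))
        for k in range(2):
            d = b - mu[k]
            q = np.einsum("ni,ij,nj->n", d, sig_inv[k], d)
            _, logdet = np.linalg.slogdet(sig[k])
            logp[:, k] = np.log(w[k]) - 0.5 * (logdet + q)
        pr1 = 1.0 / (1.0 + np.exp(np.clip(logp[:, 0] - logp[:, 1], -700, 700)))
        comp = (rng.random(n) < pr1).astype(np.int64)

        # weights
        counts = np.bincount(comp, minlength=2)
        g = rng.gamma(cfg.dirichlet_alpha + counts)
        w = g / g.sum()

        # component means and covariances
        for k in range(2):
            members = b[comp == k]
            nk = len(members)
            prec_mu = nk * sig_inv[k] + prior_prec_mu * eye2
            rhs_mu = sig_inv[k] @ members.sum(axis=0) if nk else np.zeros(2)
            mu[k] = _sample_mvn2(rng, prec_mu[None], rhs_mu[None])[0]
            d = members - mu[k]
            scale = eye2 + d.T @ d
            sig[k] = invwishart.rvs(df=cfg.wishart_df + nk, scale=scale, random_state=rng)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and s_idx < S:
            out_beta[s_idx] = beta
            out_w[s_idx] = w
            out_mu[s_idx] = mu
            out_sig[s_idx] = sig
            s_idx += 1

    return out_beta[:s_idx], out_w[:s_idx], out_mu[:s_idx], out_sig[:s_idx]


def _relabel(w, mu, sig):
    """Order components by the sum of their mean intercepts (ascending)."""
    key = mu.sum(axis=2)                        # (S, 2)
    swap = key[:, 0] > key[:, 1]
    w[swap] = w[swap][:, ::-1]
    mu[swap] = mu[swap][:, ::-1]
    sig[swap] = sig[swap][:, ::-1]
    return w, mu, sig


def _split_rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction over (n_chains, n_draws) sequences."""
    import arviz as az
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(split[None].transpose(1, 0, 2)[:, 0, :]))


def fit_mcmc(instances: Sequence[PredictionInstance], spec: ModelSpec,
             mcmc: MCMCConfig | None = None, seed: int = 0) -> PosteriorFit:
    """Fit the bivariate mixture GLMM to one prognostic group's histories.

    Runs ``mcmc.n_chains`` independent chains (distinct substreams of
    ``seed``), resolves label switching by reordering components on the sum
    of mean intercepts, stacks the retained draws, and computes a split-R̂
    diagnostic per fixed effect.  Identical (data, spec, config, seed) give
    identical draws.
    """
    cfg = mcmc or MCMCConfig()
    if len(instances) < 30:
        raise ValueError(f"need at least 30 patients, got {len(instances)}")
    X, y, pat = _pack(instances, spec)
    for e in range(2):
        if y[:, e].min() == y[:, e].max():
            raise ValueError(
                f"complete separation: all {EYES[e]}-eye outcomes are "
                f"{int(y[0, e])}; the model is not estimable")

    # centre covariates for sampling: removes the posterior correlation
    # between near-constant covariates and the mixture means; the sampled
    # means are shifted back to the raw parameterization afterwards
    center = X.mean(axis=0) if X.shape[1] else np.zeros(0)
    Xc = X - center

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_chains)
    per_chain = []
    for c, child in enumerate(children):
        np_seed, pg_seed = child.generate_state(2)
        per_chain.append(_run_chain(Xc, y, pat, len(instances), spec, cfg,
                                    int(np_seed), int(pg_seed % (2 ** 31))))
        logger.info("chain %d/%d finished (%d draws)", c + 1, cfg.n_chains,
                    per_chain[-1][0].shape[0])

    beta = np.concatenate([pc[0] for pc in per_chain])
    w = np.concatenate([pc[1] for pc in per_chain])
    mu = np.concatenate([pc[2] for pc in per_chain])
    sig = np.concatenate([pc[3] for pc in per_chain])
    if X.shape[1]:
        # raw-scale means: b_raw ~ N(mu - center.beta, Sigma)
        mu -= np.einsum("j,sje->se", center, beta)[:, None, :]
    w, mu, sig = _relabel(w, mu, sig)

    rhat: dict[str, float] = {}
    S = per_chain[0][0].shape[0]
    for j, name in enumerate(spec.covariates):
        for e, eye in enumerate(EYES):
            chains = np.stack([pc[0][:, j, e] for pc in per_chain])
            rhat[f"{name}_{eye}"] = _split_rhat(chains[:, :S])
    worst = max(rhat.values(), default=1.0)
    if worst > cfg.rhat_threshold:
        warnings.warn(f"possible non-convergence: max split-Rhat {worst:.3f} "
                      f"exceeds {cfg.rhat_threshold}", stacklevel=2)

    return PosteriorFit(spec=spec, beta=beta, weights=w, means=mu, covariances=sig,
                        config=cfg, seed=seed, n_patients=len(instances), rhat=rhat)


# ---------------------------------------------------------------------------
# reporting and model comparison
# ---------------------------------------------------------------------------

def posterior_odds_ratios(fit: PosteriorFit, spec: ModelSpec | None = None):
    """Odds-ratio table: posterior median and central 95% credible interval.

    Coefficients are already on the reporting scale (e.g. per 5 years of
    duration), so the OR per scaled unit is ``exp(coefficient)``.
    """
    import pandas as pd
    spec = spec or fit.spec
    if fit.n_draws < 100:
        raise ValueError("need at least 100 retained draws for credible intervals")
    rows = []
    for j, name in enumerate(spec.covariates):
        unit = COVARIATE_SCALINGS[name][2]
        for e, eye in enumerate(EYES):
            ors = np.exp(fit.beta[:, j, e])
            lo, med, hi = np.percentile(ors, [2.5, 50.0, 97.5])
            rows.append((name, unit, eye, med, lo, hi))
    return pd.DataFrame(rows, columns=["covariate", "unit", "eye", "or", "ci_lo", "ci_hi"])


def penalized_expected_deviance(fit: PosteriorFit,
                                instances: Sequence[PredictionInstance],
                                n_draws: int = 50) -> float:
    """Expected deviance plus an effective-parameter complexity penalty.

    Deviance is -2 times the log marginal likelihood of the data (random
    intercepts integrated over the mixture).  The criterion is
    ``Dbar + pD = 2 Dbar - D(theta_bar)`` with ``pD = Dbar - D(theta_bar)``
    evaluated at the posterior mean — an expected-deviance criterion with a
    complexity penalty, deterministic given the retained draws (an evenly
    spaced subset of ``n_draws`` is used).  Lower is better.
    """
    from .discriminant import cohort_log_likelihood
    idx = fit.thin_indices(n_draws)
    dev = np.array([-2.0 * cohort_log_likelihood(instances, fit.params_at(s), fit.spec)
                    for s in idx])
    dbar = dev.mean()
    d_at_mean = -2.0 * cohort_log_likelihood(instances, fit.posterior_mean_params(), fit.spec)
    return float(2.0 * dbar - d_at_mean)


def forward_select(candidates: Sequence[str], forced: Sequence[str],
                   instances: Sequence[PredictionInstance],
                   mcmc: MCMCConfig | None = None, seed: int = 0,
                   share_eyes: bool = False, ped_draws: int = 50,
                   criterion_fn=None) -> ModelSpec:
    """Greedy forward covariate selection under penalized expected deviance.

    Starts from the forced covariates (always retained, e.g. HbA1c kept on
    clinical grounds), then repeatedly adds the candidate with the largest
    criterion improvement, stopping when no addition improves it.
    ``criterion_fn`` (a covariate list -> score map, lower is better)
    replaces the fit-and-PED criterion when supplied.
    """
    selected = list(forced)
    remaining = [c for c in candidates if c not in selected]

    def criterion(covs: list[str]) -> float:
        if criterion_fn is not None:
            return criterion_fn(covs)
        spec = ModelSpec(covariates=tuple(covs), share_eyes=share_eyes)
        fit = fit_mcmc(instances, spec, mcmc, seed=seed)
        return penalized_expected_deviance(fit, instances, n_draws=ped_draws)

    best = criterion(selected)
    logger.info("forward selection: start %s, PED %.2f", selected, best)
    while remaining:
        scores = {c: criterion(selected + [c]) for c in remaining}
        cand = min(scores, key=scores.get)
        if scores[cand] >= best:
            break
        best = scores[cand]
        selected.append(cand)
        remaining.remove(cand)
        logger.info("forward selection: added %s, PED %.2f", cand, best)
    return ModelSpec(covariates=tuple(selected), share_eyes=share_eyes)
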