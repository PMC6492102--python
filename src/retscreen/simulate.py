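"""Synthetic screening-cohort generator.

Generates cohorts with the statistical structure the discriminant analysis
assumes: each patient belongs to one of two prognostic groups (develops STDR
within a year of their final visit, or not), and within a group the per-eye
binary grade trajectory follows that group's bivariate logistic mixed model
with a two-component mixture random-intercept pair.  The default effect sizes
are the published odds ratios of the screening study the package models
(duration OR 2.25 per 5 y, type 1 OR 2.44, time OR 0.97/y, SBP OR 1.07 per
10 mmHg, HbA1c OR 1.04 per 10 mmol/mol in the non-STDR group; duration OR
1.78 per 5 y, missed-appointment OR 2.12, time OR 1.60/y in the STDR group),
and the demographic/covariate distributions are calibrated to that study's
cohort table (n = 13 103, 2.6% STDR, median follow-up ~6 years, annual visits,
missed-visit rates 4.3% vs 23.5%).

Mixture means and covariances are not published; the defaults here keep the
published component weights (low-risk weight 0.362 in the non-STDR group,
high-risk weight 0.292 in the STDR group) and are calibrated so the grade
distributions at the prediction visit approximate the cohort table
(R1/R1 ~74% in the STDR group vs ~8% in the non-STDR group).

The generator has no mechanism for STDR onset (the study does not publish
one): STDR-group patients are assigned an STDR grade at their final visit,
whose time is uniform over the follow-up range.  Every patient's first and
final scheduled visits are attended; intermediate visits are missed with the
group-specific probability.

Randomness: one global seed; each patient uses an independent substream
spawned from it, so enlarging the cohort leaves earlier patients unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .cohort import (GRADE_R0, GRADE_R1, GRADE_STDR, CovariateRecord,
                     PatientRecord, ScreeningEpisode, write_cohort)
from .glmm import COVARIATE_SCALINGS, MixtureGLMMParams, ModelSpec, inverse_logit

GROUP_STDR = "STDR"
GROUP_NONSTDR = "non-STDR"

_AR_RHO = 0.7  # within-patient autocorrelation of clinical series


@dataclass
class GroupTruth:
    """Ground-truth model of one prognostic group: covariate set + parameters."""

    spec: ModelSpec
    params: MixtureGLMMParams


def _truth(covariates, ors, weights, means, covs) -> GroupTruth:
    spec = ModelSpec(covariates=tuple(covariates), share_eyes=True)
    beta = np.log(np.asarray(ors, dtype=float))
    params = MixtureGLMMParams(
        beta=np.column_stack([beta, beta]),
        weights=np.asarray(weights, dtype=float),
        means=np.asarray(means, dtype=float),
        covariances=np.asarray(covs, dtype=float))
    params.validate()
    return GroupTruth(spec=spec, params=params)


def default_truth_nonstdr() -> GroupTruth:
    """Non-STDR-group truth: published ORs; low-risk component weight 0.362."""
    return _truth(
        covariates=("duration", "type1", "time", "sbp", "hba1c"),
        ors=(2.25, 2.44, 0.97, 1.07, 1.04),
        weights=(0.362, 0.638),
        means=((-7.0, -7.0), (-3.9, -3.9)),
        covs=(((0.8, 0.7), (0.7, 0.8)), ((2.0, 1.8), (1.8, 2.0))))


def default_truth_stdr() -> GroupTruth:
    """STDR-group truth: published ORs; high-risk component weight 0.292."""
    return _truth(
        covariates=("duration", "missed_prev", "time", "hba1c"),
        ors=(1.78, 2.12, 1.60, 1.0),
        weights=(0.708, 0.292),
        means=((-1.6, -1.6), (0.8, 0.8)),
        covs=(((1.3, 1.15), (1.15, 1.3)), ((1.3, 1.15), (1.15, 1.3))))


def default_covariate_distributions() -> dict[str, dict[str, Any]]:
    """Group-conditional demographic/clinical distributions.

    Normal variables are ``[patient_mean_loc, patient_sd, within_sd]``;
    right-skewed ones (duration of diabetes at entry, HbA1c) are shifted
    log-normals ``[shift, mu, sigma]`` moment-fitted to the published
    median/IQR.
    """
    return {
        GROUP_NONSTDR: {
            "age": [59.65, 13.27], "female_prob": 0.419, "type1_prob": 0.046,
            "duration_lognorm": [-1.766, 1.2827, 0.840],
            "hba1c_lognorm": [32.0, 2.890, 0.601], "hba1c_within_sd": 4.0,
            "sbp": [131.47, 12.0, 8.0], "dbp": [75.16, 7.0, 6.0],
            "chol": [4.18, 0.9, 0.4],
        },
        GROUP_STDR: {
            "age": [52.93, 14.43], "female_prob": 0.349, "type1_prob": 0.194,
            "duration_lognorm": [-2.151, 1.960, 0.706],
            "hba1c_lognorm": [31.9, 3.529, 0.712], "hba1c_within_sd": 4.0,
            "sbp": [134.27, 12.5, 8.0], "dbp": [77.09, 7.0, 6.0],
            "chol": [4.25, 0.95, 0.4],
        },
    }


@dataclass
class GeneratorConfig:
    n_patients: int = 13_103
    prevalence_stdr: float = 0.026
    visit_gap_years: float = 1.0
    visit_gap_jitter: float = 0.1
    followup_min: float = 2.0
    followup_max: float = 10.0
    miss_prob_nonstdr: float = 0.043
    miss_prob_stdr: float = 0.235
    covariate_missing_prob: float = 0.0
    covariate_distributions: dict = field(default_factory=default_covariate_distributions)
    truth_nonstdr: GroupTruth = field(default_factory=default_truth_nonstdr)
    truth_stdr: GroupTruth = field(default_factory=default_truth_stdr)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.prevalence_stdr < 1.0:
            raise ValueError("prevalence must be strictly inside (0, 1): "
                             "both prognostic groups are required")
        if self.followup_min < 2.0:
            raise ValueError("minimum follow-up is 2 years")
        for p in (self.miss_prob_nonstdr, self.miss_prob_stdr):
            if not 0.0 <= p < 1.0:
                raise ValueError("miss probabilities must be in [0, 1)")
        self.truth_nonstdr.params.validate()
        self.truth_stdr.params.validate()

    def to_dict(self) -> dict:
        def truth_dict(t: GroupTruth) -> dict:
            return {"covariates": list(t.spec.covariates),
                    "beta": t.params.beta.tolist(),
                    "weights": t.params.weights.tolist(),
                    "means": t.params.means.tolist(),
                    "covariances": t.params.covariances.tolist()}
        d = {k: getattr(self, k) for k in
             ("n_patients", "prevalence_stdr", "visit_gap_years", "visit_gap_jitter",
              "followup_min", "followup_max", "miss_prob_nonstdr", "miss_prob_stdr",
              "covariate_missing_prob", "seed")}
        d["covariate_distributions"] = self.covariate_distributions
        d["truth_nonstdr"] = truth_dict(self.truth_nonstdr)
        d["truth_stdr"] = truth_dict(self.truth_stdr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("truth_nonstdr", "truth_stdr"):
            if key in d and isinstance(d[key], dict):
                t = d[key]
                d[key] = GroupTruth(
                    spec=ModelSpec(covariates=tuple(t["covariates"]), share_eyes=True),
                    params=MixtureGLMMParams(
                        beta=np.asarray(t["beta"], dtype=float),
                        weights=np.asarray(t["weights"], dtype=float),
                        means=np.asarray(t["means"], dtype=float),
                        covariances=np.asarray(t["covariances"], dtype=float)))
        return cls(**d)


# ---------------------------------------------------------------------------
# per-patient sampling
# ---------------------------------------------------------------------------

def _shifted_lognormal(rng, shift, mu, sigma):
    return max(0.0, shift + float(rng.lognormal(mu, sigma)))


def _ar1_series(rng, n, within_sd, rho=_AR_RHO):
    e = np.empty(n)
    e[0] = rng.normal(0.0, within_sd)
    for j in range(1, n):
        e[j] = rho * e[j - 1] + rng.normal(0.0, within_sd * np.sqrt(1.0 - rho ** 2))
    return e


def sample_patient_covariates(config: GeneratorConfig, rng: np.random.Generator,
                              group: str) -> dict[str, Any]:
    """Demographics, follow-up schedule and longitudinal covariate series for
    one patient of the given prognostic group."""
    dist = config.covariate_distributions[group]
    age = float(np.clip(rng.normal(*dist["age"]), 18.0, 95.0))
    sex = "female" if rng.random() < dist["female_prob"] else "male"
    dtype = "type1" if rng.random() < dist["type1_prob"] else "type2"
    duration0 = _shifted_lognormal(rng, *dist["duration_lognorm"])

    followup = float(rng.uniform(config.followup_min, config.followup_max))
    times = [0.0]
    while True:
        gap = float(np.clip(rng.normal(config.visit_gap_years, config.visit_gap_jitter),
                            0.5, 1.5))
        if times[-1] + gap >= followup - 0.25:
            break
        times.append(times[-1] + gap)
    times.append(followup)
    n = len(times)

    hb_shift, hb_mu, hb_sigma = dist["hba1c_lognorm"]
    hba1c = max(20.0, hb_shift + float(rng.lognormal(hb_mu, hb_sigma))) \
        + _ar1_series(rng, n, dist["hba1c_within_sd"])
    series = {"hba1c": np.maximum(hba1c, 20.0)}
    for var in ("sbp", "dbp", "chol"):
        loc, psd, wsd = dist[var]
        series[var] = rng.normal(loc, psd) + _ar1_series(rng, n, wsd)
    series["chol"] = np.maximum(series["chol"], 1.0)

    miss_prob = config.miss_prob_stdr if group == GROUP_STDR else config.miss_prob_nonstdr
    attended = rng.random(n) >= miss_prob
    attended[0] = attended[-1] = True   # first and final visits are recorded

    return {"age": age, "sex": sex, "diabetes_type": dtype, "duration0": duration0,
            "times": np.array(times), "attended": attended, "series": series,
            "followup": followup}


def _design_row(truth: GroupTruth, cov: dict, j: int, missed_prev: float) -> np.ndarray:
    raw = {
        "duration": cov["duration0"] + cov["times"][j],
        "type1": float(cov["diabetes_type"] == "type1"),
        "time": cov["times"][j],
        "sbp": cov["series"]["sbp"][j],
        "hba1c": cov["series"]["hba1c"][j],
        "missed_prev": missed_prev,
        "dbp": cov["series"]["dbp"][j],
        "chol": cov["series"]["chol"][j],
        "sex_male": float(cov["sex"] == "male"),
        "age": cov["age"] + cov["times"][j],
    }
    return np.array([raw[name] / COVARIATE_SCALINGS[name][1]
                     for name in truth.spec.covariates])


def simulate_grade_trajectory(cov: dict, truth: GroupTruth,
                              rng: np.random.Generator,
                              is_stdr_group: bool) -> tuple[list[ScreeningEpisode], dict]:
    """Per-eye R0/R1 trajectory for one patient given group-truth parameters.

    A mixture component is drawn, then a random-intercept pair (right, left);
    each attended visit's eye grades are Bernoulli draws on the logit scale.
    STDR-group patients receive an STDR grade at their final visit.
    """
    params = truth.params
    k = int(rng.random() >= params.weights[0])
    z = rng.standard_normal(2)
    if np.abs(params.covariances[k]).max() < 1e-12:
        b = params.means[k].copy()
    else:
        b = params.means[k] + np.linalg.cholesky(params.covariances[k]) @ z

    episodes: list[ScreeningEpisode] = []
    times, attended = cov["times"], cov["attended"]
    n = len(times)
    for j in range(n):
        if not attended[j]:
            episodes.append(ScreeningEpisode(time=float(times[j]), grade_right=None,
                                             grade_left=None, attended=False))
            continue
        if is_stdr_group and j == n - 1:
            sides = rng.random()
            gr = GRADE_STDR if sides < 0.7 else GRADE_R1
            gl = GRADE_STDR if sides > 0.3 else GRADE_R1
            episodes.append(ScreeningEpisode(time=float(times[j]), grade_right=gr,
                                             grade_left=gl, attended=True))
            continue
        missed_prev = 0.0 if j == 0 else float(not attended[j - 1])
        x = _design_row(truth, cov, j, missed_prev)
        eta = x @ np.atleast_2d(params.beta) + b
        y = rng.random(2) < inverse_logit(eta)
        episodes.append(ScreeningEpisode(
            time=float(times[j]),
            grade_right=GRADE_R1 if y[0] else GRADE_R0,
            grade_left=GRADE_R1 if y[1] else GRADE_R0,
            attended=True))
    return episodes, {"component": k, "b_right": float(b[0]), "b_left": float(b[1])}


def _make_patient(config: GeneratorConfig, pid: str, rng: np.random.Generator,
                  group: str | None = None) -> tuple[PatientRecord, dict]:
    if group is None:
        group = GROUP_STDR if rng.random() < config.prevalence_stdr else GROUP_NONSTDR
    cov = sample_patient_covariates(config, rng, group)
    truth = config.truth_stdr if group == GROUP_STDR else config.truth_nonstdr
    episodes, btruth = simulate_grade_trajectory(cov, truth, rng, group == GROUP_STDR)

    records = []
    for j, t in enumerate(cov["times"]):
        tc = float(max(0.0, t + rng.normal(0.0, 0.08))) if j else 0.0
        vals = {}
        for var in ("hba1c", "sbp", "dbp", "chol"):
            miss = rng.random() < config.covariate_missing_prob
            vals[var] = np.nan if miss else float(cov["series"][var][j])
        records.append(CovariateRecord(time=tc, **vals))

    patient = PatientRecord(
        patient_id=pid, sex=cov["sex"], age_at_first_visit=cov["age"],
        diabetes_type=cov["diabetes_type"],
        duration_at_first_visit=cov["duration0"],
        episodes=episodes, covariates=records)
    truth_rec = {"group": group, **btruth}
    return patient, truth_rec


def simulate_cohort(config: GeneratorConfig,
                    group: str | None = None) -> tuple[list[PatientRecord], dict[str, dict]]:
    """Generate a cohort in memory; ``group`` forces every patient's group
    (useful for single-group fitting experiments)."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients, truth = [], {}
    width = len(str(config.n_patients))
    for i, ss in enumerate(streams):
        pid = f"P{i:0{width}d}"
        p, t = _make_patient(config, pid, np.random.default_rng(ss), group)
        patients.append(p)
        truth[pid] = t
    return patients, truth


def generate_cohort(config: GeneratorConfig, out_dir: str | Path,
                    group: str | None = None) -> dict[str, str]:
    """Generate a cohort and write episode/covariate/demographic CSVs, the
    per-patient truth JSON, the config used, and a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, truth = simulate_cohort(config, group=group)
    paths = {name: out / f"{name}.csv" for name in ("episodes", "covariates", "demographics")}
    write_cohort(patients, paths["episodes"], paths["covariates"], paths["demographics"])
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    config_path = out / "generator_config.json"
    config_path.write_text(json.dumps(config.to_dict(), indent=1))
    files = {**{k: str(v) for k, v in paths.items()},
             "truth": str(truth_path), "config": str(config_path)}
    manifest = {name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
                for name, p in files.items()}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps({"seed": config.seed, "sha256": manifest},
                                        indent=1))
    files["manifest"] = str(manifest_path)
    return files
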