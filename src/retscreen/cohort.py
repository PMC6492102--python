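"""Cohort data model, file I/O, exclusion filters and prediction instances.

The unit of observation is the screening *episode*: one scheduled retinal
photography appointment, which, if attended, yields a per-eye retinopathy
grade.  Grades are coarsened to three states — ``R0`` (no retinopathy
detected), ``R1`` (mild non-proliferative / background retinopathy, not
referable) and ``STDR`` (sight-threatening retinopathy, the referral-triggering
endpoint).  The longitudinal models work on the R0/R1 binary transition; STDR
is the terminal event whose detection defines a patient's final visit.

Episodes live on a per-patient clock: time is measured in years since that
patient's first screening episode.  Time-varying clinical covariates (HbA1c,
systolic/diastolic blood pressure, total cholesterol) are recorded on their
own visit grid and aligned to screening episodes by nearest-in-time matching.

A :class:`PredictionInstance` is one patient's usable history truncated one
year (the prediction horizon) before their final visit, together with the
known outcome: whether STDR was detected within the following year.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("retscreen")

GRADE_R0 = "R0"
GRADE_R1 = "R1"
GRADE_STDR = "STDR"
GRADES = (GRADE_R0, GRADE_R1, GRADE_STDR)

COVARIATE_VARS = ("hba1c", "sbp", "dbp", "chol")

#: soft physiological plausibility ranges (warn, never reject)
_SOFT_RANGES = {"hba1c": (20.0, 200.0), "sbp": (70.0, 260.0)}

#: grace added to the prediction cutoff so the episode scheduled ~1 year
#: before the final visit is retained despite scheduling jitter (the recall
#: window for missed appointments is about 6 weeks; 0.25 y is one quarter)
PREDICTION_GRACE_YEARS = 0.25


class SchemaError(ValueError):
    """A cohort file is missing a mandatory column."""


@dataclass
class ScreeningEpisode:
    """One scheduled screening appointment of one patient."""

    time: float
    grade_right: str | None
    grade_left: str | None
    attended: bool

    def has_stdr(self) -> bool:
        return self.attended and GRADE_STDR in (self.grade_right, self.grade_left)


@dataclass
class CovariateRecord:
    time: float
    hba1c: float = np.nan
    sbp: float = np.nan
    dbp: float = np.nan
    chol: float = np.nan


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    age_at_first_visit: float
    diabetes_type: str
    duration_at_first_visit: float
    episodes: list[ScreeningEpisode] = field(default_factory=list)
    covariates: list[CovariateRecord] = field(default_factory=list)

    def attended_episodes(self) -> list[ScreeningEpisode]:
        return [e for e in self.episodes if e.attended]


@dataclass
class PredictionInstance:
    """A patient's modelling history plus the known 1-year outcome.

    ``times``/``grades`` cover the attended, covariate-complete episodes at or
    before the prediction visit (``grades`` is 0/1 per eye, column order
    right, left); ``covariates`` holds the aligned covariate matrix for those
    same episodes.  ``episodes`` additionally keeps every *scheduled* row up
    to the prediction visit so the grade-based stratification rules can see
    missed appointments.
    """

    patient_id: str
    prediction_time: float
    times: np.ndarray
    grades: np.ndarray
    covariates: pd.DataFrame
    episodes: list[ScreeningEpisode]
    missed_previous: bool
    label: bool
    sex: str = "female"
    diabetes_type: str = "type2"
    age_at_first_visit: float = np.nan
    duration_at_first_visit: float = np.nan

    @property
    def n_visits(self) -> int:
        return len(self.times)


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts, in application order."""

    n_input: int
    n_output: int
    counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"n_input": self.n_input, "n_output": self.n_output, "excluded": self.counts},
            indent=2))


@dataclass
class ParseReport:
    n_rows: dict[str, int]
    rejected: list[tuple[int, str]]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_EPISODE_COLS = ["patient_id", "time_years", "grade_right", "grade_left", "attended"]
_COVARIATE_COLS = ["patient_id", "time_years", "hba1c_mmol_mol", "sbp_mmhg",
                   "dbp_mmhg", "chol_mmol_l"]
_DEMOGRAPHIC_COLS = ["patient_id", "sex", "age_first_visit", "diabetes_type",
                     "duration_first_visit_years"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{what} file is missing mandatory column '{c}'")


def read_cohort(episodes_path: str | Path, covariates_path: str | Path,
                demographics_path: str | Path) -> tuple[list[PatientRecord], ParseReport]:
    """Read the three cohort CSV files into :class:`PatientRecord` objects.

    Episode rows with an unknown grade code are rejected (dropped) and listed
    in the parse report with their 1-based line number; a missing mandatory
    column raises :class:`SchemaError`.
    """
    epi = pd.read_csv(episodes_path, dtype={"patient_id": str})
    cov = pd.read_csv(covariates_path, dtype={"patient_id": str})
    dem = pd.read_csv(demographics_path, dtype={"patient_id": str})
    _require_columns(epi, _EPISODE_COLS, "episodes")
    _require_columns(cov, _COVARIATE_COLS, "covariates")
    _require_columns(dem, _DEMOGRAPHIC_COLS, "demographics")

    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(epi), dtype=bool)
    attended = epi["attended"].astype(int).to_numpy() == 1
    for col in ("grade_right", "grade_left"):
        vals = epi[col].astype("string")
        bad = attended & ~vals.isin(GRADES).to_numpy(na_value=False)
        for idx in np.flatnonzero(bad):
            # +2: header line plus 1-based indexing
            rejected.append((int(idx) + 2, f"unparseable grade '{vals.iloc[idx]}' in {col}"))
        keep &= ~bad
    epi = epi[keep]

    for var, (lo, hi) in _SOFT_RANGES.items():
        col = {"hba1c": "hba1c_mmol_mol", "sbp": "sbp_mmhg"}[var]
        vals = cov[col].to_numpy(dtype=float)
        n_odd = int(np.sum((vals < lo) | (vals > hi)))
        if n_odd:
            warnings.warn(f"{n_odd} {var} values outside plausible range [{lo}, {hi}]",
                          stacklevel=2)

    patients: list[PatientRecord] = []
    epi_by_pid = {pid: g for pid, g in epi.groupby("patient_id", sort=False)}
    cov_by_pid = {pid: g for pid, g in cov.groupby("patient_id", sort=False)}
    for row in dem.itertuples(index=False):
        pid = row.patient_id
        p = PatientRecord(
            patient_id=pid, sex=str(row.sex),
            age_at_first_visit=float(row.age_first_visit),
            diabetes_type=str(row.diabetes_type),
            duration_at_first_visit=float(row.duration_first_visit_years))
        g = epi_by_pid.get(pid)
        if g is not None:
            g = g.sort_values("time_years")
            for r in g.itertuples(index=False):
                att = int(r.attended) == 1
                p.episodes.append(ScreeningEpisode(
                    time=float(r.time_years),
                    grade_right=str(r.grade_right) if att else None,
                    grade_left=str(r.grade_left) if att else None,
                    attended=att))
        c = cov_by_pid.get(pid)
        if c is not None:
            c = c.sort_values("time_years")
            for r in c.itertuples(index=False):
                p.covariates.append(CovariateRecord(
                    time=float(r.time_years), hba1c=float(r.hba1c_mmol_mol),
                    sbp=float(r.sbp_mmhg), dbp=float(r.dbp_mmhg),
                    chol=float(r.chol_mmol_l)))
        if p.episodes:
            patients.append(p)

    report = ParseReport(
        n_rows={"episodes": len(epi), "covariates": len(cov), "demographics": len(dem)},
        rejected=rejected)
    logger.info("read cohort: %d patients, %d episode rows, %d rejected rows",
                len(patients), len(epi), len(rejected))
    return patients, report


def write_cohort(patients: Iterable[PatientRecord], episodes_path: str | Path,
                 covariates_path: str | Path, demographics_path: str | Path) -> None:
    """Write patients back to the three-CSV cohort layout (read_cohort inverse)."""
    epi_rows, cov_rows, dem_rows = [], [], []
    for p in patients:
        dem_rows.append((p.patient_id, p.sex, p.age_at_first_visit,
                         p.diabetes_type, p.duration_at_first_visit))
        for e in p.episodes:
            epi_rows.append((p.patient_id, e.time,
                             e.grade_right if e.attended else "",
                             e.grade_left if e.attended else "",
                             int(e.attended)))
        for c in p.covariates:
            cov_rows.append((p.patient_id, c.time, c.hba1c, c.sbp, c.dbp, c.chol))
    pd.DataFrame(epi_rows, columns=_EPISODE_COLS).to_csv(episodes_path, index=False)
    pd.DataFrame(cov_rows, columns=_COVARIATE_COLS).to_csv(covariates_path, index=False)
    pd.DataFrame(dem_rows, columns=_DEMOGRAPHIC_COLS).to_csv(demographics_path, index=False)


# ---------------------------------------------------------------------------
# covariate alignment
# ---------------------------------------------------------------------------

def align_covariates(patient: PatientRecord, episode_times: Sequence[float]) -> pd.DataFrame:
    """Assign each episode the covariate values nearest in time.

    Each variable is aligned independently over the records where it is
    observed.  When two records are equally distant, the earlier one is used.
    Episodes for which some required variable has no record at all are
    flagged ``usable = False`` (they are excluded from model fitting, not
    imputed).
    """
    episode_times = np.asarray(list(episode_times), dtype=float)
    out = pd.DataFrame({"time": episode_times})
    usable = np.ones(len(episode_times), dtype=bool)
    cov_times = np.array([c.time for c in patient.covariates], dtype=float)
    for var in COVARIATE_VARS:
        vals = np.array([getattr(c, var) for c in patient.covariates], dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            out[var] = np.nan
            usable[:] = False
            continue
        t_ok, v_ok = cov_times[ok], vals[ok]
        dist = np.abs(episode_times[:, None] - t_ok[None, :])
        # stable argmin over records sorted by time -> earlier record wins ties
        order = np.argsort(t_ok, kind="stable")
        pick = order[np.argmin(dist[:, order], axis=1)]
        out[var] = v_ok[pick]
    out["usable"] = usable
    return out


# ---------------------------------------------------------------------------
# exclusions, final visit, prediction instances
# ---------------------------------------------------------------------------

EXCLUSION_RULES = ("single_visit", "no_recent_clinical_visit", "stdr_at_start")


def apply_exclusions(patients: Sequence[PatientRecord],
                     window_years: float = 1.5) -> tuple[list[PatientRecord], ExclusionReport]:
    """Apply the cohort exclusion filters, counting each patient once.

    In order: (1) patients with fewer than two attended episodes; (2) patients
    with no clinical (covariate) record within ``window_years`` (18 months)
    before their final attended visit; (3) patients already graded STDR at
    their first attended episode.
    """
    counts = dict.fromkeys(EXCLUSION_RULES, 0)
    kept: list[PatientRecord] = []
    for p in patients:
        attended = p.attended_episodes()
        if len(attended) < 2:
            counts["single_visit"] += 1
            continue
        final_time = attended[-1].time
        cov_times = [c.time for c in p.covariates
                     if not all(np.isnan(getattr(c, v)) for v in COVARIATE_VARS)]
        if not cov_times or max(cov_times) < final_time - window_years:
            counts["no_recent_clinical_visit"] += 1
            continue
        if attended[0].has_stdr():
            counts["stdr_at_start"] += 1
            continue
        kept.append(p)
    report = ExclusionReport(n_input=len(patients), n_output=len(kept), counts=counts)
    logger.info("exclusions: %s (kept %d/%d)", counts, len(kept), len(patients))
    return kept, report


def define_final_visit_and_label(patient: PatientRecord) -> tuple[float, str]:
    """Final visit time and prognostic group.

    If STDR is ever detected (either eye), the final visit is the earliest
    such episode and the patient belongs to the STDR group; data beyond STDR
    detection are ignored.  Otherwise the final visit is the last attended
    episode and the patient is non-STDR.
    """
    for e in patient.attended_episodes():
        if e.has_stdr():
            return e.time, "STDR"
    return patient.attended_episodes()[-1].time, "non-STDR"


def _binary_grade(grade: str) -> int:
    return {GRADE_R0: 0, GRADE_R1: 1}[grade]


def build_prediction_instances(patients: Sequence[PatientRecord],
                               horizon: float = 1.0,
                               grace: float = PREDICTION_GRACE_YEARS,
                               ) -> list[PredictionInstance]:
    """Truncate each patient's history ``horizon`` years before the final visit.

    The prediction visit is the last attended episode at or before
    ``final_time - horizon + grace``; the label records whether the patient's
    final visit (one horizon later) carried STDR.  Patients whose truncated
    history has no covariate-complete attended episode are dropped with a
    warning.
    """
    instances: list[PredictionInstance] = []
    n_dropped = 0
    for p in patients:
        final_time, group = define_final_visit_and_label(p)
        cutoff = final_time - horizon + grace
        sched = [e for e in p.episodes if e.time <= cutoff and not e.has_stdr()]
        attended = [e for e in sched if e.attended]
        if not attended:
            n_dropped += 1
            continue
        prediction_time = attended[-1].time
        sched = [e for e in sched if e.time <= prediction_time + 1e-9]
        aligned = align_covariates(p, [e.time for e in attended])
        usable = aligned["usable"].to_numpy()
        if not usable.any():
            n_dropped += 1
            continue
        # scheduled row immediately before the prediction visit, if any
        before = [e for e in sched if e.time < prediction_time - 1e-9]
        missed_previous = bool(before) and not before[-1].attended

        # per-episode missed-previous indicator over the full schedule
        miss_ind = []
        for e in attended:
            prior = [s for s in sched if s.time < e.time - 1e-9]
            miss_ind.append(bool(prior) and not prior[-1].attended)

        covars = aligned.copy()
        covars["missed_prev"] = np.asarray(miss_ind, dtype=float)
        covars["duration"] = p.duration_at_first_visit + covars["time"]
        covars["type1"] = float(p.diabetes_type == "type1")
        covars["sex_male"] = float(p.sex == "male")
        covars["age"] = p.age_at_first_visit + covars["time"]
        covars = covars[usable].reset_index(drop=True)

        grades = np.array([[_binary_grade(e.grade_right), _binary_grade(e.grade_left)]
                           for e, u in zip(attended, usable) if u], dtype=int)
        times = np.array([e.time for e, u in zip(attended, usable) if u])
        instances.append(PredictionInstance(
            patient_id=p.patient_id, prediction_time=prediction_time,
            times=times, grades=grades, covariates=covars, episodes=sched,
            missed_previous=missed_previous, label=(group == "STDR"),
            sex=p.sex, diabetes_type=p.diabetes_type,
            age_at_first_visit=p.age_at_first_visit,
            duration_at_first_visit=p.duration_at_first_visit))
    if n_dropped:
        logger.warning("dropped %d patients with empty truncated history", n_dropped)
    return instances
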