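"""Grade-based screening-interval rules the discriminant model is compared to.

Two simple allocation rules, each mapping a patient to *low risk* (offered
biennial screening, predicted not to develop STDR within 1 year) or *high
risk* (kept on annual screening):

* **two-episode rule** — low risk only if the two most recent successive
  annual screening episodes were both attended and showed no retinopathy in
  either eye (four R0 grades).  A missed episode forces high risk, since the
  rule cannot be evaluated.
* **current-episode rule** — low risk if neither eye shows retinopathy at the
  prediction-time episode alone.

Both rules use retinopathy level only; covariates never enter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import GRADE_R0, PredictionInstance, ScreeningEpisode

#: two successive *annual* episodes: a gap beyond this means one was missed
#: (annual schedule plus the ~6-week recall window for missed appointments)
MAX_ANNUAL_GAP_YEARS = 1.25

LOW_RISK = "low_risk"
HIGH_RISK = "high_risk"


@dataclass
class RuleAllocation:
    patient_id: str
    rule: str                 # "two_episode" | "current_episode"
    allocation: str           # LOW_RISK -> biennial, HIGH_RISK -> annual
    rationale: str            # e.g. ALL_R0, R1_PRESENT, MISSED_EPISODE


def _is_r0_both_eyes(episode: ScreeningEpisode) -> bool:
    return episode.grade_right == GRADE_R0 and episode.grade_left == GRADE_R0


def rule_two_episode(instance: PredictionInstance) -> RuleAllocation:
    """Low risk iff the last two scheduled episodes were attended, at most
    ~1 year apart, and all four eye grades are R0."""
    sched = instance.episodes
    if len(sched) < 2:
        return RuleAllocation(instance.patient_id, "two_episode", HIGH_RISK,
                              "SINGLE_EPISODE")
    last, prev = sched[-1], sched[-2]
    if not (last.attended and prev.attended):
        return RuleAllocation(instance.patient_id, "two_episode", HIGH_RISK,
                              "MISSED_EPISODE")
    if last.time - prev.time > MAX_ANNUAL_GAP_YEARS:
        return RuleAllocation(instance.patient_id, "two_episode", HIGH_RISK,
                              "MISSED_EPISODE")
    if _is_r0_both_eyes(last) and _is_r0_both_eyes(prev):
        return RuleAllocation(instance.patient_id, "two_episode", LOW_RISK, "ALL_R0")
    return RuleAllocation(instance.patient_id, "two_episode", HIGH_RISK, "R1_PRESENT")


def rule_current_episode(instance: PredictionInstance) -> RuleAllocation:
    """Low risk iff both eyes are R0 at the prediction-time episode."""
    sched = instance.episodes
    last = sched[-1] if sched else None
    if last is None or not last.attended:
        return RuleAllocation(instance.patient_id, "current_episode", HIGH_RISK,
                              "MISSED_EPISODE")
    if _is_r0_both_eyes(last):
        return RuleAllocation(instance.patient_id, "current_episode", LOW_RISK, "ALL_R0")
    return RuleAllocation(instance.patient_id, "current_episode", HIGH_RISK, "R1_PRESENT")


def allocate_cohort(instances: Sequence[PredictionInstance]
                    ) -> list[RuleAllocation]:
    """Both rules for every patient (two allocations per patient)."""
    out = []
    for inst in instances:
        out.append(rule_two_episode(inst))
        out.append(rule_current_episode(inst))
    return out


def allocations_frame(allocations: Sequence[RuleAllocation]):
    import pandas as pd
    return pd.DataFrame(
        [(a.patient_id, a.rule, a.allocation, a.rationale) for a in allocations],
        columns=["patient_id", "rule", "allocation", "rationale"])
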