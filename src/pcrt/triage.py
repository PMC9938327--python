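"""Per-patient triage outcomes and cohort funnel counts.

The two pathways are independent: the familial score drives referral to
genetic counseling, the NOD criteria drive enrollment in the high-risk
pancreatic clinic; one patient may trigger both.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict

from pcrt.endpac import EndpacAssessment, EndpacVerdict, meets_endpac_criteria, nod_assessable
from pcrt.questionnaire import PatientResponse, TriState
from pcrt.scoring import PointTable, RiskScoreResult, default_point_table, score_family_history

__all__ = ["FlowCounts", "TriageAction", "TriageOutcome", "cohort_flow", "triage_patient"]


class TriageAction(str, Enum):
    refer_genetic_counseling = "refer_genetic_counseling"
    enroll_high_risk_clinic = "enroll_high_risk_clinic"
    none = "none"


class TriageOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    famhx_refer: bool
    score: RiskScoreResult
    endpac: EndpacAssessment
    actions: frozenset[TriageAction]


class FlowCounts(BaseModel):
    """Cohort funnel tallies: scoring strata, then the NOD sub-funnel."""

    model_config = ConfigDict(frozen=True)

    n_total: int
    n_score_ge_threshold: int
    n_score_lt_threshold: int
    n_prior_genetic_testing: int
    n_preexisting_pancreatic_cancer: int
    n_nod_section_completed: int
    n_nod_unknown_glucose: int
    n_nod_unknown_weight: int
    n_nod_assessable: int
    n_endpac_met: int


def triage_patient(
    r: PatientResponse,
    t: Optional[PointTable] = None,
    min_loss_pct: int = 0,
) -> TriageOutcome:
    """Evaluate both pathways for one respondent.

    Patients with a pre-existing pancreatic-cancer diagnosis still
    receive a familial score (and may be referred) but are excluded
    from NOD-based enrollment.
    """
    score = score_family_history(r, t)
    endpac = meets_endpac_criteria(r, min_loss_pct=min_loss_pct)
    actions: set[TriageAction] = set()
    if score.refer:
        actions.add(TriageAction.refer_genetic_counseling)
    if endpac.verdict == EndpacVerdict.meets:
        actions.add(TriageAction.enroll_high_risk_clinic)
    if not actions:
        actions.add(TriageAction.none)
    return TriageOutcome(
        patient_id=r.patient_id,
        famhx_refer=score.refer,
        score=score,
        endpac=endpac,
        actions=frozenset(actions),
    )


def cohort_flow(
    cohort: Iterable[PatientResponse],
    t: Optional[PointTable] = None,
    min_loss_pct: int = 0,
) -> FlowCounts:
    """Tally the cohort funnel; every respondent counts once per stratum.

    The unknown-glucose and unknown-weight strata are counted within
    section completers only (the two may overlap); assessable counts
    completers with glucose answered and both weights known.
    """
    t = t or default_point_table()
    n_total = n_hi = n_prior = n_pc = 0
    n_completed = n_unk_glucose = n_unk_weight = n_assessable = n_met = 0
    for r in cohort:
        n_total += 1
        out = triage_patient(r, t, min_loss_pct=min_loss_pct)
        if out.famhx_refer:
            n_hi += 1
        if r.prior_genetic_testing:
            n_prior += 1
        if r.preexisting_pancreatic_cancer:
            n_pc += 1
        nod = r.nod
        if nod.section_completed:
            n_completed += 1
            if nod.glucose_elevated == TriState.unknown:
                n_unk_glucose += 1
            if nod.weight_current_lb is None or nod.weight_one_year_ago_lb is None:
                n_unk_weight += 1
            if nod_assessable(r):
                n_assessable += 1
        if out.endpac.verdict == EndpacVerdict.meets:
            n_met += 1
    return FlowCounts(
        n_total=n_total,
        n_score_ge_threshold=n_hi,
        n_score_lt_threshold=n_total - n_hi,
        n_prior_genetic_testing=n_prior,
        n_preexisting_pancreatic_cancer=n_pc,
        n_nod_section_completed=n_completed,
        n_nod_unknown_glucose=n_unk_glucose,
        n_nod_unknown_weight=n_unk_weight,
        n_nod_assessable=n_assessable,
        n_endpac_met=n_met,
    )
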