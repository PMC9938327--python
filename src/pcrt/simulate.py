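"""Synthetic questionnaire cohorts.

Two generators are provided:

* :func:`generate_cohort` draws random cohorts from configurable
  prevalences with one top-level seed and per-respondent substreams, so
  record *i* is the same regardless of cohort size.
* :func:`fixture_cohort` builds a deterministic 453-record cohort whose
  funnel tallies under the default triage reproduce a published
  clinic deployment exactly (117 high-risk, 348 NOD-completed, 128
  glucose-unknown, 16 weight-unknown, 220 assessable, 4 criteria-met,
  18 prior-tested, 6 pre-existing pancreatic cancer), including six
  named worked-example respondents.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from pcrt.errors import ConfigurationError
from pcrt.questionnaire import (
    CancerEvent,
    CancerType,
    Ethnicity,
    NODResponses,
    PatientResponse,
    PersonHistory,
    Relation,
    Sex,
    TriState,
)

__all__ = ["CohortConfig", "fixture_cohort", "generate_cohort", "load_cohort_config"]


def _prob(default: float) -> float:
    return Field(default=default, ge=0.0, le=1.0)


class CohortConfig(BaseModel):
    """Marginal prevalences and distributions for the random generator."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=453, ge=0)
    seed: int = 0

    # family structure and cancer events
    event_probabilities: dict[str, dict[CancerType, float]] = Field(
        default_factory=lambda: {
            "self": {CancerType.breast: 0.04, CancerType.colorectal: 0.03,
                     CancerType.prostate: 0.03, CancerType.melanoma: 0.03,
                     CancerType.thyroid: 0.01, CancerType.pancreatic: 0.012,
                     CancerType.other: 0.05},
            "mother": {CancerType.breast: 0.08, CancerType.ovarian: 0.02,
                       CancerType.colorectal: 0.04, CancerType.pancreatic: 0.02,
                       CancerType.other: 0.06},
            "father": {CancerType.prostate: 0.08, CancerType.colorectal: 0.04,
                       CancerType.pancreatic: 0.02, CancerType.melanoma: 0.02,
                       CancerType.other: 0.06},
            "sibling": {CancerType.breast: 0.03, CancerType.colorectal: 0.02,
                        CancerType.pancreatic: 0.01, CancerType.other: 0.03},
        }
    )
    p_dx_le50_given_event: float = _prob(0.3)
    mean_siblings: float = Field(default=1.5, ge=0.0)
    ashkenazi_prevalence: float = _prob(0.05)
    p_both_parents_given_ashkenazi: float = _prob(0.25)

    # NOD section
    nod_section_completion_rate: float = _prob(0.77)
    glucose_unknown_rate: float = _prob(0.37)
    weight_unknown_rate: float = _prob(0.12)  # nested within the glucose-unknown stratum
    glucose_elevated_rate: float = _prob(0.15)
    glycemic_change_given_elevated: float = _prob(0.6)
    weight_change_mean_pct: float = 0.0
    weight_change_sd_pct: float = Field(default=4.0, ge=0.0)

    # demographics and flags
    preexisting_pc_rate: float = _prob(0.013)
    prior_testing_rate: float = _prob(0.04)
    diabetes_rate: float = _prob(0.24)
    smoking_rate: float = _prob(0.07)
    female_rate: float = _prob(0.554)
    age_median: float = 65.0
    age_iqr: float = Field(default=18.0, gt=0.0)


def load_cohort_config(path: str | Path) -> CohortConfig:
    try:
        return CohortConfig.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))
    except (OSError, ValueError) as exc:
        raise ConfigurationError(f"cannot load cohort config from {path}: {exc}") from exc


def _tri(flag: bool) -> TriState:
    return TriState.yes if flag else TriState.no


def _draw_events(rng: np.random.Generator, probs: dict[CancerType, float], p_le50: float
                 ) -> list[CancerEvent]:
    events = []
    for ctype, p in probs.items():
        if rng.random() < p:
            le50 = TriState.yes if rng.random() < p_le50 else TriState.no
            events.append(CancerEvent(cancer_type=ctype, dx_at_or_before_50=le50))
    return events


def _generate_one(cfg: CohortConfig, i: int) -> PatientResponse:
    # substream per respondent: inserting a record never perturbs the others
    rng = np.random.default_rng([cfg.seed, i])

    persons = [
        PersonHistory(
            relation=Relation.self,
            events=_draw_events(rng, cfg.event_probabilities.get("self", {}),
                                cfg.p_dx_le50_given_event),
        )
    ]
    for rel in (Relation.mother, Relation.father):
        ev = _draw_events(rng, cfg.event_probabilities.get(rel.value, {}),
                          cfg.p_dx_le50_given_event)
        if ev:
            persons.append(PersonHistory(relation=rel, events=ev))
    n_sib = int(rng.poisson(cfg.mean_siblings))
    for k in range(1, n_sib + 1):
        ev = _draw_events(rng, cfg.event_probabilities.get("sibling", {}),
                          cfg.p_dx_le50_given_event)
        if ev:
            persons.append(PersonHistory(relation=Relation.sibling, relation_index=k, events=ev))

    ashkenazi = rng.random() < cfg.ashkenazi_prevalence
    both = ashkenazi and rng.random() < cfg.p_both_parents_given_ashkenazi

    completed = rng.random() < cfg.nod_section_completion_rate
    if completed:
        glucose_unknown = rng.random() < cfg.glucose_unknown_rate
        weight_unknown = glucose_unknown and rng.random() < cfg.weight_unknown_rate
        prev_w = float(np.round(rng.normal(180.0, 35.0), 0))
        prev_w = max(prev_w, 90.0)
        pct = rng.normal(cfg.weight_change_mean_pct, cfg.weight_change_sd_pct)
        cur_w = float(np.round(prev_w * (1.0 + pct / 100.0), 0))
        cur_w = max(cur_w, 80.0)
        if glucose_unknown:
            glucose = TriState.unknown
        else:
            glucose = _tri(rng.random() < cfg.glucose_elevated_rate)
        if glucose == TriState.yes:
            glycemic = _tri(rng.random() < cfg.glycemic_change_given_elevated)
        elif glucose == TriState.no:
            glycemic = TriState.no
        else:
            glycemic = TriState.unknown
        nod = NODResponses(
            section_completed=True,
            weight_current_lb=cur_w,
            weight_one_year_ago_lb=None if weight_unknown else prev_w,
            glucose_elevated=glucose,
            diabetes_or_glucose_intolerance=bool(rng.random() < cfg.diabetes_rate),
            glycemic_change_around_age_50_or_later=glycemic,
        )
    else:
        # keep the stream length stable across strata
        rng.random(size=4)
        rng.normal(size=2)
        nod = NODResponses(
            section_completed=False,
            diabetes_or_glucose_intolerance=bool(rng.random() < cfg.diabetes_rate),
        )

    age = int(np.clip(round(rng.normal(cfg.age_median, cfg.age_iqr / 1.349)), 18, 100))
    sex = Sex.female if rng.random() < cfg.female_rate else Sex.male
    eth = Ethnicity(
        str(rng.choice(["White", "African American", "Asian", "Other"],
                       p=[0.90, 0.06, 0.015, 0.025]))
    )
    return PatientResponse(
        patient_id=f"S{i:05d}",
        age=age,
        sex=sex,
        ethnicity=eth,
        ashkenazi_mother=_tri(ashkenazi),
        ashkenazi_father=_tri(both),
        current_smoker=bool(rng.random() < cfg.smoking_rate),
        prior_genetic_testing=bool(rng.random() < cfg.prior_testing_rate),
        preexisting_pancreatic_cancer=bool(rng.random() < cfg.preexisting_pc_rate),
        persons=persons,
        nod=nod,
    )


def generate_cohort(cfg: CohortConfig) -> list[PatientResponse]:
    """Draw a random cohort; bit-identical for identical (cfg, seed)."""
    return [_generate_one(cfg, i) for i in range(cfg.n)]


# --------------------------------------------------------------------------
# Deterministic fixture


def _self_only(*events: CancerEvent) -> list[PersonHistory]:
    return [PersonHistory(relation=Relation.self, events=list(events))]


def _nod_met(cur: float, prev: float) -> NODResponses:
    return NODResponses(
        weight_current_lb=cur,
        weight_one_year_ago_lb=prev,
        glucose_elevated=TriState.yes,
        diabetes_or_glucose_intolerance=True,
        glycemic_change_around_age_50_or_later=TriState.yes,
    )


def _nod_assessable_not_met(cur: float = 170.0, prev: float = 170.0) -> NODResponses:
    return NODResponses(
        weight_current_lb=cur,
        weight_one_year_ago_lb=prev,
        glucose_elevated=TriState.no,
        glycemic_change_around_age_50_or_later=TriState.no,
    )


def _nod_unknown_glucose(weight_known: bool, cur: float = 172.0, prev: float = 175.0
                         ) -> NODResponses:
    return NODResponses(
        weight_current_lb=cur,
        weight_one_year_ago_lb=prev if weight_known else None,
        glucose_elevated=TriState.unknown,
        glycemic_change_around_age_50_or_later=TriState.unknown,
    )


def _nod_not_completed() -> NODResponses:
    return NODResponses(section_completed=False)


def _vignettes() -> list[PatientResponse]:
    """The six worked-example respondents (scores 8, 6, 6, 6, 1, 3)."""
    ev = CancerEvent
    ct, ts = CancerType, TriState
    return [
        # score 8: personal thyroid; sibling breast <=50; mother ovarian <=50
        PatientResponse(
            patient_id="V-RET", age=54, sex=Sex.female,
            persons=[
                PersonHistory(relation=Relation.self,
                              events=[ev(cancer_type=ct.thyroid, dx_at_or_before_50=ts.no)]),
                PersonHistory(relation=Relation.sibling, relation_index=1,
                              events=[ev(cancer_type=ct.breast, dx_at_or_before_50=ts.yes)]),
                PersonHistory(relation=Relation.mother,
                              events=[ev(cancer_type=ct.ovarian, dx_at_or_before_50=ts.yes)]),
            ],
            nod=_nod_assessable_not_met(),
        ),
        # score 6: Ashkenazi mother with pancreatic cancer; father with prostate cancer
        PatientResponse(
            patient_id="V-ATM", age=65, sex=Sex.female,
            ashkenazi_mother=ts.yes, ashkenazi_father=ts.no,
            persons=[
                PersonHistory(relation=Relation.self),
                PersonHistory(relation=Relation.mother,
                              events=[ev(cancer_type=ct.pancreatic, dx_at_or_before_50=ts.no)]),
                PersonHistory(relation=Relation.father,
                              events=[ev(cancer_type=ct.prostate, dx_at_or_before_50=ts.no)]),
            ],
            nod=_nod_assessable_not_met(),
        ),
        # score 6: both parents Ashkenazi; mother breast and colon cancer at/before 50
        PatientResponse(
            patient_id="V-APC", age=75, sex=Sex.male,
            ashkenazi_mother=ts.yes, ashkenazi_father=ts.yes,
            persons=[
                PersonHistory(relation=Relation.self),
                PersonHistory(relation=Relation.mother, events=[
                    ev(cancer_type=ct.breast, dx_at_or_before_50=ts.yes),
                    ev(cancer_type=ct.colorectal, dx_at_or_before_50=ts.yes),
                ]),
            ],
            nod=_nod_assessable_not_met(),
        ),
        # score 6: personal pancreatic cancer; mother breast cancer at/before 50
        PatientResponse(
            patient_id="V-SDHA", age=67, sex=Sex.female,
            preexisting_pancreatic_cancer=True,
            persons=[
                PersonHistory(relation=Relation.self,
                              events=[ev(cancer_type=ct.pancreatic, dx_at_or_before_50=ts.no)]),
                PersonHistory(relation=Relation.mother,
                              events=[ev(cancer_type=ct.breast, dx_at_or_before_50=ts.yes)]),
            ],
            nod=_nod_assessable_not_met(),
        ),
        # score 1: father with colorectal cancer; met NOD criteria (209 vs 242 lb)
        PatientResponse(
            patient_id="V-NOD1", age=59, sex=Sex.female,
            persons=[
                PersonHistory(relation=Relation.self),
                PersonHistory(relation=Relation.father,
                              events=[ev(cancer_type=ct.colorectal, dx_at_or_before_50=ts.no)]),
            ],
            nod=_nod_met(209.0, 242.0),
        ),
        # score 3: sibling with pancreatic cancer; met NOD criteria (175 vs 183 lb)
        PatientResponse(
            patient_id="V-NOD2", age=81, sex=Sex.female,
            prior_genetic_testing=True,
            persons=[
                PersonHistory(relation=Relation.self),
                PersonHistory(relation=Relation.sibling, relation_index=1,
                              events=[ev(cancer_type=ct.pancreatic, dx_at_or_before_50=ts.no)]),
            ],
            nod=_nod_met(175.0, 183.0),
        ),
    ]


def fixture_cohort() -> list[PatientResponse]:
    """Deterministic 453-record cohort reproducing the published funnel.

    Guaranteed tallies under default triage: 117 score >= 3, 18 prior
    genetic testing (3 of them low-risk), 6 pre-existing pancreatic
    cancer, 348 NOD-section completers, of whom 128 glucose-unknown
    (16 also weight-unknown), 220 assessable and 4 criteria-met.
    Unconstrained fields are filled from a fixed seed.
    """
    rng = np.random.default_rng(20230116)
    cohort = _vignettes()
    ev, ct, ts = CancerEvent, CancerType, TriState

    # familial-risk plan for the 447 filler records
    plans: list[dict] = []
    for _ in range(5):  # high-risk with pre-existing pancreatic cancer
        plans.append({"kind": "hi_pc"})
    for _ in range(14):  # high-risk, Ashkenazi mother with pancreatic cancer
        plans.append({"kind": "hi_aj"})
    for _ in range(93):  # high-risk, mother with pancreatic cancer
        plans.append({"kind": "hi"})
    for _ in range(7):  # low-risk, Ashkenazi ancestry only (score 2)
        plans.append({"kind": "low_aj"})
    for _ in range(2):  # low-risk, met NOD criteria (score 1)
        plans.append({"kind": "low_met"})
    for _ in range(80):  # low-risk, father with colorectal cancer (score 1)
        plans.append({"kind": "low_1"})
    for _ in range(246):  # low-risk, no family scoring factors
        plans.append({"kind": "low_0"})
    assert len(plans) == 447

    # personal-history flavor matching the published group summary: 38
    # high-risk and 46 low-risk respondents with a personal cancer history
    # (self melanoma scores 1, self breast without the age flag adds 1)
    n_self_hi, n_self_lo = 0, 0
    for plan in plans:
        if plan["kind"] == "hi" and n_self_hi < 31:
            plan["self_event"] = ct.breast
            n_self_hi += 1
        elif plan["kind"] == "low_0" and n_self_lo < 46:
            plan["self_event"] = ct.melanoma
            n_self_lo += 1

    # NOD strata for fillers: the two low_met records are fixed; hi_pc records
    # are assessable; the rest are dealt out to hit the printed funnel.
    remaining = {"assessable": 207, "unk_glucose": 112, "unk_both": 16, "not_completed": 105}
    deck: list[str] = []
    for stratum, k in remaining.items():
        deck += [stratum] * k
    rng.shuffle(deck)
    di = 0

    prior_hi_left, prior_low_left = 14, 3  # V-NOD2 is the 15th high-risk prior-tested

    # demographic counters (vignette contributions already subtracted):
    # females 67 high / 184 low, diabetes 32 high / 72 low, smoking 10 / 23,
    # ethnicity split per the published group summary
    fem = {"hi": 63, "low": 183}
    dia = {"hi": 31, "low": 69}  # the two low_met fillers report diabetes already
    smoke = {"hi": 10, "low": 23}
    eth = {
        "hi": [("African American", 4), ("Asian", 2), ("Other", 3), ("White", 103)],
        "low": [("African American", 23), ("Asian", 4), ("Other", 5), ("White", 303)],
    }

    def take(counters: dict, group: str) -> bool:
        if counters[group] > 0:
            counters[group] -= 1
            return True
        return False

    def take_eth(group: str) -> str:
        for i, (name, k) in enumerate(eth[group]):
            if k > 0:
                eth[group][i] = (name, k - 1)
                return name
        return "White"

    for plan in plans:
        kind = plan["kind"]
        group = "hi" if kind.startswith("hi") else "low"
        persons = [PersonHistory(relation=Relation.self)]
        aj_mother = aj_father = ts.no
        preexisting = False
        if kind == "hi_pc":
            persons = _self_only(ev(cancer_type=ct.pancreatic, dx_at_or_before_50=ts.no))
            preexisting = True
        elif kind == "hi_aj":
            aj_mother = ts.yes
            persons.append(PersonHistory(relation=Relation.mother,
                                         events=[ev(cancer_type=ct.pancreatic,
                                                    dx_at_or_before_50=ts.no)]))
        elif kind == "hi":
            persons.append(PersonHistory(relation=Relation.mother,
                                         events=[ev(cancer_type=ct.pancreatic,
                                                    dx_at_or_before_50=ts.no)]))
        elif kind == "low_aj":
            aj_mother = ts.yes
        elif kind in ("low_met", "low_1"):
            persons.append(PersonHistory(relation=Relation.father,
                                         events=[ev(cancer_type=ct.colorectal,
                                                    dx_at_or_before_50=ts.no)]))
        if "self_event" in plan:
            persons[0] = PersonHistory(
                relation=Relation.self,
                events=list(persons[0].events)
                + [ev(cancer_type=plan["self_event"], dx_at_or_before_50=ts.no)],
            )

        if kind == "low_met":
            nod = _nod_met(cur=150.0, prev=165.0)
        elif kind == "hi_pc":
            nod = _nod_assessable_not_met()
        else:
            stratum = deck[di]
            di += 1
            if stratum == "assessable":
                nod = _nod_assessable_not_met()
            elif stratum == "unk_glucose":
                nod = _nod_unknown_glucose(weight_known=True)
            elif stratum == "unk_both":
                nod = _nod_unknown_glucose(weight_known=False)
            else:
                nod = _nod_not_completed()
        if kind != "low_met" and take(dia, group):
            nod = nod.model_copy(update={"diabetes_or_glucose_intolerance": True})

        prior = False
        if kind in ("hi_aj", "hi") and prior_hi_left > 0:
            prior, prior_hi_left = True, prior_hi_left - 1
        elif kind == "low_0" and prior_low_left > 0:
            prior, prior_low_left = True, prior_low_left - 1

        i = len(cohort) + 1
        cohort.append(
            PatientResponse(
                patient_id=f"F{i:04d}",
                age=int(np.clip(round(rng.normal(66.0 if group == "hi" else 63.0, 13.0)),
                                18, 95)),
                sex=Sex.female if take(fem, group) else Sex.male,
                ethnicity=Ethnicity(take_eth(group)),
                ashkenazi_mother=aj_mother,
                ashkenazi_father=aj_father,
                current_smoker=take(smoke, group),
                prior_genetic_testing=prior,
                preexisting_pancreatic_cancer=preexisting,
                persons=persons,
                nod=nod,
            )
        )
    assert di == len(deck)
    assert prior_hi_left == 0 and prior_low_left == 0
    return cohort
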