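"""New-onset-diabetes (ENDPAC-criteria) assessment from questionnaire items.

The operational rule flags respondents with any self-reported weight
loss together with self-reported higher-than-normal blood glucose
around age 50 or later, excluding those already diagnosed with
pancreatic cancer.  A fully parameterized three-component point model
can be supplied via config; none is shipped.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict

from pcrt.errors import ConfigurationError
from pcrt.questionnaire import PatientResponse, TriState

__all__ = [
    "EndpacAssessment",
    "EndpacPointModel",
    "EndpacVerdict",
    "PointBin",
    "endpac_score",
    "load_endpac_model",
    "meets_endpac_criteria",
    "nod_assessable",
    "percent_weight_change",
]


class EndpacVerdict(str, Enum):
    meets = "meets"
    does_not_meet = "does_not_meet"
    not_assessable = "not_assessable"
    excluded_prior_pc = "excluded_prior_pc"


class EndpacAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    assessable: bool
    weight_change_pct: Optional[int] = None
    glucose_flag: Optional[bool] = None
    verdict: EndpacVerdict


def percent_weight_change(current_lb: float, previous_lb: float) -> int:
    """Integer percent change in body weight; loss is negative.

    Rounds half away from zero, so (209, 242) -> -14 and (175, 183) -> -4.
    """
    if current_lb <= 0 or previous_lb <= 0:
        raise ValueError(f"weights must be positive, got ({current_lb}, {previous_lb})")
    pct = Decimal(100) * (Decimal(str(current_lb)) - Decimal(str(previous_lb))) / Decimal(
        str(previous_lb)
    )
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def nod_assessable(r: PatientResponse) -> bool:
    """True when the NOD items suffice: glucose answered and both weights known.

    Respondents who never completed the section are not assessable (and
    are outside the section-completed denominator in the funnel).
    """
    nod = r.nod
    return (
        nod.section_completed
        and nod.glucose_elevated != TriState.unknown
        and nod.weight_current_lb is not None
        and nod.weight_one_year_ago_lb is not None
    )


def meets_endpac_criteria(r: PatientResponse, min_loss_pct: int = 0) -> EndpacAssessment:
    """Assess the questionnaire-level criteria for one respondent.

    Precedence: a pre-existing pancreatic-cancer diagnosis excludes the
    respondent outright; insufficient NOD answers give not_assessable;
    otherwise the respondent meets the criteria iff they report weight
    loss (strictly below zero, and at least ``min_loss_pct`` percent
    when configured) AND elevated glucose AND a glycemic change around
    age 50 or later.
    """
    nod = r.nod
    wc = None
    if nod.weight_current_lb is not None and nod.weight_one_year_ago_lb is not None:
        wc = percent_weight_change(nod.weight_current_lb, nod.weight_one_year_ago_lb)
    glucose = None if nod.glucose_elevated == TriState.unknown else (
        nod.glucose_elevated == TriState.yes
    )

    if r.preexisting_pancreatic_cancer:
        verdict = EndpacVerdict.excluded_prior_pc
    elif not nod_assessable(r):
        verdict = EndpacVerdict.not_assessable
    else:
        assert wc is not None and glucose is not None
        met = (
            wc < 0
            and wc <= -min_loss_pct
            and glucose
            and nod.glycemic_change_around_age_50_or_later == TriState.yes
        )
        verdict = EndpacVerdict.meets if met else EndpacVerdict.does_not_meet

    return EndpacAssessment(
        patient_id=r.patient_id,
        assessable=nod_assessable(r),
        weight_change_pct=wc,
        glucose_flag=glucose,
        verdict=verdict,
    )


class PointBin(BaseModel):
    """Half-open bin [min, max) carrying integer points; null bounds are open."""

    model_config = ConfigDict(frozen=True)

    min: Optional[float] = None
    max: Optional[float] = None
    points: int

    def contains(self, x: float) -> bool:
        return (self.min is None or x >= self.min) and (self.max is None or x < self.max)


class EndpacPointModel(BaseModel):
    """Config-supplied three-component point model; no default is shipped."""

    model_config = ConfigDict(frozen=True)

    age_bins: tuple[PointBin, ...]
    weight_bins: tuple[PointBin, ...]
    glucose_bins: tuple[PointBin, ...]
    threshold: int


def load_endpac_model(path: str | Path) -> EndpacPointModel:
    try:
        return EndpacPointModel.model_validate(
            json.loads(Path(path).read_text(encoding="utf-8"))
        )
    except (OSError, ValueError) as exc:
        raise ConfigurationError(f"cannot load ENDPAC point model from {path}: {exc}") from exc


def _bin_points(bins: tuple[PointBin, ...], x: float, component: str) -> int:
    for b in bins:
        if b.contains(x):
            return b.points
    raise ConfigurationError(f"value {x} falls in no configured {component} bin")


def endpac_score(
    age_at_glycemic_onset: float,
    weight_change_pct: float,
    glucose_change: float,
    model: Optional[EndpacPointModel],
) -> tuple[int, bool]:
    """Sum the three components' bin points under a user-supplied model.

    Returns (score, score >= model.threshold).  The published model is
    not redistributed; supply its bins as a JSON config (see Sharma et
    al. 2018 for the parameterization).
    """
    if model is None:
        raise ConfigurationError(
            "no ENDPAC point model configured; supply bins and threshold as JSON"
            " (parameterization published by Sharma et al. 2018)"
        )
    score = (
        _bin_points(model.age_bins, age_at_glycemic_onset, "age")
        + _bin_points(model.weight_bins, weight_change_pct, "weight-change")
        + _bin_points(model.glucose_bins, glucose_change, "glucose-change")
    )
    return score, score >= model.threshold
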