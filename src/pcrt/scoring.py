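"""Point-based familial cancer-risk score and referral decision.

Every cancer event on the respondent or a first-degree relative scores
its base points, plus an age-modifier when the diagnosis was at or
before age 50; Ashkenazi ancestry in either parent adds one flat bonus.
A total at or above the referral threshold indicates referral to
genetic counseling.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from pcrt.errors import ConfigurationError
from pcrt.questionnaire import CancerType, PatientResponse, PersonHistory, Relation, TriState

__all__ = [
    "PointTable",
    "RiskScoreResult",
    "ScoreContribution",
    "default_point_table",
    "explain_score",
    "load_point_table",
    "score_family_history",
]

ANCESTRY_SOURCE = "ancestry"


class PointTable(BaseModel):
    """Configurable cancer-to-points map with threshold.

    ``age_modifier_points`` are added on top of the base points when the
    event's at-or-before-50 flag is yes (unknown scores base only).
    """

    model_config = ConfigDict(frozen=True)

    base_points: dict[CancerType, int]
    age_modifier_points: dict[CancerType, int]
    ancestry_bonus: int = Field(ge=0)
    referral_threshold: int = Field(ge=1)

    def event_points(self, cancer_type: CancerType, dx_at_or_before_50: TriState) -> int:
        if cancer_type not in self.base_points:
            raise ConfigurationError(f"no base points configured for {cancer_type.value!r}")
        pts = self.base_points[cancer_type]
        if dx_at_or_before_50 == TriState.yes:
            pts += self.age_modifier_points.get(cancer_type, 0)
        return pts


def default_point_table() -> PointTable:
    """The default table, the minimal completion consistent with the
    published worked examples (pancreatic 3; breast 1 plus 2 when at or
    before 50; referral at a total of 3 or more)."""
    zero = {c: 0 for c in CancerType}
    return PointTable(
        base_points={
            CancerType.pancreatic: 3,
            CancerType.ovarian: 3,
            CancerType.thyroid: 2,
            CancerType.breast: 1,
            CancerType.colorectal: 1,
            CancerType.prostate: 1,
            CancerType.melanoma: 1,
            CancerType.other: 0,
        },
        age_modifier_points={**zero, CancerType.breast: 2},
        ancestry_bonus=2,
        referral_threshold=3,
    )


def load_point_table(path: str | Path) -> PointTable:
    """Load a point table from a flat JSON config file."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return PointTable.model_validate(doc)
    except (OSError, ValueError) as exc:
        raise ConfigurationError(f"cannot load point table from {path}: {exc}") from exc


class ScoreContribution(BaseModel):
    """One addend of the total: a person's event, or the ancestry bonus."""

    model_config = ConfigDict(frozen=True)

    source: str  # "self", "mother", "father", "sibling 2", or "ancestry"
    factor: str  # cancer type value or "ancestry"
    dx_at_or_before_50: TriState = TriState.unknown
    points: int


class RiskScoreResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    total: int
    contributions: tuple[ScoreContribution, ...]
    refer: bool


def _source_name(p: PersonHistory) -> str:
    if p.relation == Relation.sibling and p.relation_index:
        return f"sibling {p.relation_index}"
    return p.relation.value


def score_family_history(r: PatientResponse, t: Optional[PointTable] = None) -> RiskScoreResult:
    """Score a respondent's personal and family cancer history.

    Personal and family events score identically; each event contributes
    independently (no cap); the ancestry bonus is applied once if either
    parent is Ashkenazi.  Deterministic and order-preserving.
    """
    t = t or default_point_table()
    contributions: list[ScoreContribution] = []
    for p in r.persons:
        src = _source_name(p)
        for ev in p.events:
            contributions.append(
                ScoreContribution(
                    source=src,
                    factor=ev.cancer_type.value,
                    dx_at_or_before_50=ev.dx_at_or_before_50,
                    points=t.event_points(ev.cancer_type, ev.dx_at_or_before_50),
                )
            )
    if TriState.yes in (r.ashkenazi_mother, r.ashkenazi_father):
        contributions.append(
            ScoreContribution(source=ANCESTRY_SOURCE, factor=ANCESTRY_SOURCE, points=t.ancestry_bonus)
        )
    total = sum(c.points for c in contributions)
    return RiskScoreResult(
        patient_id=r.patient_id,
        total=total,
        contributions=tuple(contributions),
        refer=total >= t.referral_threshold,
    )


def explain_score(res: RiskScoreResult) -> str:
    """Human-readable itemization whose lines sum to the total."""
    lines = []
    for c in res.contributions:
        if c.source == ANCESTRY_SOURCE:
            lines.append(f"Ashkenazi ancestry: +{c.points}")
        else:
            age = " (dx at or before 50)" if c.dx_at_or_before_50 == TriState.yes else ""
            lines.append(f"{c.source}: {c.factor} cancer{age}: +{c.points}")
    if not lines:
        lines.append("no scoring factors")
    lines.append(f"total: {res.total} -> {'refer' if res.refer else 'no referral'}")
    return "\n".join(lines)
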