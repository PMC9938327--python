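"""Questionnaire data model with validation and lossless JSON/CSV I/O.

The model captures one respondent's demographics, personal and
first-degree-relative cancer events (with an at-or-before-50 diagnosis
flag), Ashkenazi ancestry per parent, and the new-onset-diabetes (NOD)
items: current weight, weight one year ago, and fasting-glucose-change
awareness.

Missing-data convention: an unanswered item is always represented as
``unknown`` (tri-state) or ``None`` (weights), never coerced to "no".
Downstream triage depends on the distinction.
"""

from __future__ import annotations

import csv
import json
import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional

import pydantic
from pydantic import BaseModel, ConfigDict, Field

from pcrt.errors import CohortParseError, DuplicatePatientIdError

__all__ = [
    "CancerEvent",
    "CancerType",
    "Ethnicity",
    "NODResponses",
    "PatientResponse",
    "PersonHistory",
    "Relation",
    "Sex",
    "TriState",
    "ValidationIssue",
    "ValidationReport",
    "cohort_json_schema",
    "read_cohort",
    "validate_response",
    "write_cohort",
]


class TriState(str, Enum):
    """Yes / no / unknown answer to a questionnaire item."""

    yes = "yes"
    no = "no"
    unknown = "unknown"


class CancerType(str, Enum):
    pancreatic = "pancreatic"
    breast = "breast"
    ovarian = "ovarian"
    colorectal = "colorectal"
    prostate = "prostate"
    thyroid = "thyroid"
    melanoma = "melanoma"
    other = "other"


class Relation(str, Enum):
    self = "self"
    mother = "mother"
    father = "father"
    sibling = "sibling"


class Sex(str, Enum):
    female = "female"
    male = "male"
    other = "other"


class Ethnicity(str, Enum):
    white = "White"
    african_american = "African American"
    asian = "Asian"
    other = "Other"


class CancerEvent(BaseModel):
    """One cancer diagnosis reported for a person.

    ``other`` carries an optional free-text label and scores zero under
    the default point table.
    """

    model_config = ConfigDict(frozen=True)

    cancer_type: CancerType
    dx_at_or_before_50: TriState = TriState.unknown
    label: Optional[str] = None


class PersonHistory(BaseModel):
    """Cancer events for one person in the respondent's first-degree circle.

    ``relation_index`` distinguishes multiple siblings (1-based); it is 0
    for self, mother and father.
    """

    model_config = ConfigDict(frozen=True)

    relation: Relation
    relation_index: int = 0
    events: tuple[CancerEvent, ...] = ()

    @pydantic.field_validator("events", mode="before")
    @classmethod
    def _coerce_events(cls, v: object) -> object:
        return tuple(v) if isinstance(v, list) else v


class NODResponses(BaseModel):
    """New-onset-diabetes questionnaire section.

    ``section_completed`` is False when the section was never answered;
    such respondents fall outside the NOD funnel denominator entirely.
    Weights are in pounds; ``None`` means the respondent could not recall.
    """

    model_config = ConfigDict(frozen=True)

    section_completed: bool = True
    weight_current_lb: Optional[float] = None
    weight_one_year_ago_lb: Optional[float] = None
    glucose_elevated: TriState = TriState.unknown
    diabetes_or_glucose_intolerance: bool = False
    glycemic_change_around_age_50_or_later: TriState = TriState.unknown


class PatientResponse(BaseModel):
    """One respondent's full questionnaire record."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age: int
    sex: Sex
    ethnicity: Ethnicity = Ethnicity.white
    ashkenazi_mother: TriState = TriState.unknown
    ashkenazi_father: TriState = TriState.unknown
    current_smoker: bool = False
    prior_genetic_testing: bool = False
    preexisting_pancreatic_cancer: bool = False
    persons: tuple[PersonHistory, ...] = Field(default_factory=tuple)
    nod: NODResponses = Field(default_factory=NODResponses)

    @pydantic.field_validator("persons", mode="before")
    @classmethod
    def _coerce_persons(cls, v: object) -> object:
        return tuple(v) if isinstance(v, list) else v

    def person(self, relation: Relation, relation_index: int = 0) -> Optional[PersonHistory]:
        for p in self.persons:
            if p.relation == relation and p.relation_index == relation_index:
                return p
        return None

    @property
    def self_history(self) -> Optional[PersonHistory]:
        return self.person(Relation.self)


class ValidationIssue(BaseModel):
    field: str
    severity: Literal["error", "warning"]
    message: str


class ValidationReport(BaseModel):
    """Problems found in one record; an empty issue list means conformant."""

    patient_id: str
    issues: list[ValidationIssue] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)


def validate_response(r: PatientResponse) -> ValidationReport:
    """Check a record against the questionnaire invariants.

    Problems are reported, never raised: eligibility (age >= 18), weight
    positivity, the mandatory single ``self`` entry, and duplicate
    (relation, relation_index) pairs.
    """
    issues: list[ValidationIssue] = []

    def err(field: str, message: str) -> None:
        issues.append(ValidationIssue(field=field, severity="error", message=message))

    def warn(field: str, message: str) -> None:
        issues.append(ValidationIssue(field=field, severity="warning", message=message))

    if r.age < 18:
        err("age", f"age {r.age} is below the eligibility minimum of 18")

    for field in ("weight_current_lb", "weight_one_year_ago_lb"):
        w = getattr(r.nod, field)
        if w is not None and w <= 0:
            err(f"nod.{field}", f"weight must be strictly positive, got {w}")

    n_self = sum(1 for p in r.persons if p.relation == Relation.self)
    if n_self == 0:
        err("persons", "record has no relation=self entry")
    elif n_self > 1:
        err("persons", f"record has {n_self} relation=self entries; exactly one allowed")

    seen: set[tuple[Relation, int]] = set()
    for p in r.persons:
        key = (p.relation, p.relation_index)
        if key in seen:
            err(
                "persons",
                f"duplicate person entry for relation={p.relation.value}"
                f" index={p.relation_index}",
            )
        seen.add(key)
        if p.relation == Relation.sibling and p.relation_index < 1:
            warn("persons", "sibling entries should use 1-based relation_index")

    return ValidationReport(patient_id=r.patient_id, issues=issues)


def cohort_json_schema() -> dict:
    """JSON Schema for the cohort document ``{"respondents": [...]}``."""
    item = PatientResponse.model_json_schema()
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "pcrt cohort",
        "type": "object",
        "required": ["respondents"],
        "properties": {"respondents": {"type": "array", "items": item}},
    }


# --------------------------------------------------------------------------
# CSV layout
#
# One row per respondent.  Repeated groups are flattened to columns named
# <prefix>_cancer<j>_type / _le50 / _label with prefixes self, mother,
# father, sibling1, sibling2, ...  A <prefix>_recorded column marks the
# presence of a (possibly event-free) person entry so that round trips are
# lossless.  Empty string always means unknown/absent.

_SCALAR_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "ethnicity",
    "ashkenazi_mother",
    "ashkenazi_father",
    "current_smoker",
    "prior_genetic_testing",
    "preexisting_pancreatic_cancer",
    "nod_section_completed",
    "weight_current_lb",
    "weight_one_year_ago_lb",
    "glucose_elevated",
    "diabetes_or_glucose_intolerance",
    "glycemic_change_around_age_50_or_later",
]

_PREFIX_RE = re.compile(r"^(self|mother|father|sibling(\d+))_(recorded|cancer(\d+)_(type|le50|label))$")


def _prefix(p: PersonHistory) -> str:
    if p.relation == Relation.sibling:
        return f"sibling{p.relation_index}"
    return p.relation.value


def _bool_to_cell(b: bool) -> str:
    return "true" if b else "false"


def _cell_to_bool(s: str, where: str) -> bool:
    if s in ("true", "True", "1"):
        return True
    if s in ("false", "False", "0", ""):
        return False
    raise CohortParseError(f"{where}: cannot parse boolean value {s!r}")


def _tristate_to_cell(t: TriState) -> str:
    return "" if t == TriState.unknown else t.value


def _cell_to_tristate(s: str, where: str) -> TriState:
    if s == "":
        return TriState.unknown
    try:
        return TriState(s)
    except ValueError:
        raise CohortParseError(f"{where}: cannot parse tri-state value {s!r}") from None


def _weight_to_cell(w: Optional[float]) -> str:
    return "" if w is None else repr(w)


def _csv_columns(cohort: Iterable[PatientResponse]) -> list[str]:
    """Header for a cohort: scalar columns then person groups, widest record wins."""
    max_events: dict[str, int] = {"self": 1, "mother": 1, "father": 1}
    for r in cohort:
        for p in r.persons:
            pre = _prefix(p)
            max_events[pre] = max(max_events.get(pre, 0), len(p.events), 1)

    def sort_key(pre: str) -> tuple[int, int]:
        order = {"self": 0, "mother": 1, "father": 2}
        if pre in order:
            return (order[pre], 0)
        return (3, int(pre.removeprefix("sibling")))

    cols = list(_SCALAR_COLUMNS)
    for pre in sorted(max_events, key=sort_key):
        cols.append(f"{pre}_recorded")
        for j in range(1, max_events[pre] + 1):
            cols += [f"{pre}_cancer{j}_type", f"{pre}_cancer{j}_le50", f"{pre}_cancer{j}_label"]
    return cols


def _to_csv_row(r: PatientResponse, columns: list[str]) -> dict[str, str]:
    row = {c: "" for c in columns}
    row.update(
        patient_id=r.patient_id,
        age=str(r.age),
        sex=r.sex.value,
        ethnicity=r.ethnicity.value,
        ashkenazi_mother=_tristate_to_cell(r.ashkenazi_mother),
        ashkenazi_father=_tristate_to_cell(r.ashkenazi_father),
        current_smoker=_bool_to_cell(r.current_smoker),
        prior_genetic_testing=_bool_to_cell(r.prior_genetic_testing),
        preexisting_pancreatic_cancer=_bool_to_cell(r.preexisting_pancreatic_cancer),
        nod_section_completed=_bool_to_cell(r.nod.section_completed),
        weight_current_lb=_weight_to_cell(r.nod.weight_current_lb),
        weight_one_year_ago_lb=_weight_to_cell(r.nod.weight_one_year_ago_lb),
        glucose_elevated=_tristate_to_cell(r.nod.glucose_elevated),
        diabetes_or_glucose_intolerance=_bool_to_cell(r.nod.diabetes_or_glucose_intolerance),
        glycemic_change_around_age_50_or_later=_tristate_to_cell(
            r.nod.glycemic_change_around_age_50_or_later
        ),
    )
    for p in r.persons:
        pre = _prefix(p)
        if f"{pre}_recorded" not in row:
            raise CohortParseError(
                f"record {r.patient_id}: person group {pre!r} does not fit the header"
            )
        row[f"{pre}_recorded"] = "yes"
        for j, ev in enumerate(p.events, start=1):
            row[f"{pre}_cancer{j}_type"] = ev.cancer_type.value
            row[f"{pre}_cancer{j}_le50"] = _tristate_to_cell(ev.dx_at_or_before_50)
            row[f"{pre}_cancer{j}_label"] = ev.label or ""
    return row


def _from_csv_row(row: dict[str, str], record_no: int) -> PatientResponse:
    where = f"record {record_no}"

    def get(col: str) -> str:
        return (row.get(col) or "").strip()

    groups: dict[str, dict] = {}
    for col, raw in row.items():
        m = _PREFIX_RE.match(col)
        if not m:
            continue
        pre = m.group(1)
        g = groups.setdefault(pre, {"recorded": False, "events": {}})
        val = (raw or "").strip()
        if m.group(3) == "recorded":
            g["recorded"] = g["recorded"] or val in ("yes", "true", "1")
        else:
            j = int(m.group(4))
            g["events"].setdefault(j, {})[m.group(5)] = val

    persons: list[PersonHistory] = []
    for pre, g in groups.items():
        events = []
        for j in sorted(g["events"]):
            ev = g["events"][j]
            if not ev.get("type"):
                continue
            try:
                ctype = CancerType(ev["type"])
            except ValueError:
                raise CohortParseError(
                    f"{where}: unknown cancer type {ev['type']!r} in column group {pre}"
                ) from None
            events.append(
                CancerEvent(
                    cancer_type=ctype,
                    dx_at_or_before_50=_cell_to_tristate(ev.get("le50", ""), where),
                    label=ev.get("label") or None,
                )
            )
        if not g["recorded"] and not events:
            continue
        if pre.startswith("sibling"):
            relation, idx = Relation.sibling, int(pre.removeprefix("sibling"))
        else:
            relation, idx = Relation(pre), 0
        persons.append(PersonHistory(relation=relation, relation_index=idx, events=events))

    try:
        wc = get("weight_current_lb")
        wp = get("weight_one_year_ago_lb")
        return PatientResponse(
            patient_id=get("patient_id"),
            age=int(get("age")),
            sex=Sex(get("sex")),
            ethnicity=Ethnicity(get("ethnicity")) if get("ethnicity") else Ethnicity.white,
            ashkenazi_mother=_cell_to_tristate(get("ashkenazi_mother"), where),
            ashkenazi_father=_cell_to_tristate(get("ashkenazi_father"), where),
            current_smoker=_cell_to_bool(get("current_smoker"), where),
            prior_genetic_testing=_cell_to_bool(get("prior_genetic_testing"), where),
            preexisting_pancreatic_cancer=_cell_to_bool(
                get("preexisting_pancreatic_cancer"), where
            ),
            persons=persons,
            nod=NODResponses(
                section_completed=_cell_to_bool(get("nod_section_completed"), where),
                weight_current_lb=float(wc) if wc else None,
                weight_one_year_ago_lb=float(wp) if wp else None,
                glucose_elevated=_cell_to_tristate(get("glucose_elevated"), where),
                diabetes_or_glucose_intolerance=_cell_to_bool(
                    get("diabetes_or_glucose_intolerance"), where
                ),
                glycemic_change_around_age_50_or_later=_cell_to_tristate(
                    get("glycemic_change_around_age_50_or_later"), where
                ),
            ),
        )
    except (ValueError, pydantic.ValidationError) as exc:
        raise CohortParseError(f"{where}: {exc}") from exc


def _check_unique_ids(cohort: list[PatientResponse]) -> None:
    seen: set[str] = set()
    for r in cohort:
        if r.patient_id in seen:
            raise DuplicatePatientIdError(f"duplicate patient_id {r.patient_id!r}")
        seen.add(r.patient_id)


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise CohortParseError(f"cannot infer cohort format from path {path}")


def read_cohort(path: str | Path, format: Optional[str] = None) -> list[PatientResponse]:
    """Read a cohort file (JSON document or flat CSV) into records.

    Blank/absent answers map to ``unknown``; a duplicated patient_id
    raises :class:`DuplicatePatientIdError`; malformed content raises
    :class:`CohortParseError` naming the offending record.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise CohortParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        if not isinstance(doc, dict) or "respondents" not in doc:
            raise CohortParseError(f"{path}: expected a top-level 'respondents' array")
        cohort = []
        for i, rec in enumerate(doc["respondents"], start=1):
            try:
                cohort.append(PatientResponse.model_validate(rec))
            except pydantic.ValidationError as exc:
                raise CohortParseError(f"record {i}: {exc}") from exc
    elif fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
                raise CohortParseError(f"{path}: missing header row with patient_id column")
            cohort = [_from_csv_row(row, i) for i, row in enumerate(reader, start=1)]
    else:
        raise CohortParseError(f"unsupported cohort format {fmt!r}")
    _check_unique_ids(cohort)
    return cohort


def write_cohort(
    cohort: list[PatientResponse], path: str | Path, format: Optional[str] = None
) -> None:
    """Write a cohort so that :func:`read_cohort` round-trips it losslessly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {"respondents": [r.model_dump(mode="json") for r in cohort]}
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    elif fmt == "csv":
        columns = _csv_columns(cohort)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns)
            writer.writeheader()
            for r in cohort:
                writer.writerow(_to_csv_row(r, columns))
    else:
        raise CohortParseError(f"unsupported cohort format {fmt!r}")
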