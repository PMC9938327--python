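import pytest

from pcrt.questionnaire import (
    CancerEvent,
    CancerType,
    NODResponses,
    PatientResponse,
    PersonHistory,
    Relation,
    Sex,
    TriState,
)
from pcrt.simulate import fixture_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """The deterministic 453-record fixture cohort (built once per session)."""
    return fixture_cohort()


@pytest.fixture
def minimal_record():
    return PatientResponse(
        patient_id="P1",
        age=60,
        sex=Sex.female,
        persons=[PersonHistory(relation=Relation.self)],
    )


def make_record(
    patient_id="P1",
    age=60,
    events_by_person=(),
    ashkenazi_mother=TriState.no,
    ashkenazi_father=TriState.no,
    nod=None,
    **kwargs,
):
    """Concise record builder: events_by_person is [(relation, index, [(type, le50), ...])]."""
    persons = [PersonHistory(relation=Relation.self)]
    for rel, idx, evs in events_by_person:
        rel = Relation(rel)
        events = [
            CancerEvent(cancer_type=CancerType(t), dx_at_or_before_50=TriState(a))
            for t, a in evs
        ]
        if rel == Relation.self:
            persons[0] = PersonHistory(relation=rel, events=events)
        else:
            persons.append(PersonHistory(relation=rel, relation_index=idx, events=events))
    return PatientResponse(
        patient_id=patient_id,
        age=age,
        sex=Sex.female,
        ashkenazi_mother=ashkenazi_mother,
        ashkenazi_father=ashkenazi_father,
        persons=persons,
        nod=nod or NODResponses(),
        **kwargs,
    )
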