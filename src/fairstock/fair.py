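"""The 12-criterion FAIR compliance rubric.

The rubric adapts the FAIR guiding principles to non-scholarly livestock
data: identifiers need only be locally unique, machine-actionability is
relaxed to human-actionability, and registration in searchable resources
is not assessed.  Twelve criteria remain:

========  ==============================================  =============
criterion  meaning                                         score values
========  ==============================================  =============
F1         data identifiable through time                  0 / 0.5 / 1
F2         metadata identifiable through time              0 / 0.5 / 1
F3         data--metadata link kept up to date             0 / 0.5 / 1
A1         documented data access protocol or URL          0 / 1
A2         documented metadata access protocol or URL      0 / 1
I1         documented data structure                       0 / 1
I2         comprehensible vocabulary in the data           0 / 1
I3         documented / standard metadata structure        0 / 1
I4         comprehensible vocabulary in the metadata       0 / 1
R1         elements to (re)construct rich metadata         0 / 0.5 / 1
R2         documented collection & quality processes       0 / 0.5 / 1
R3         data and metadata licensed                      0 / 0.5 / 1
========  ==============================================  =============

An *unknown* survey answer never satisfies a condition.  A criterion is
*fulfilled* only at score 1; 0.5 is *partial*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

from .errors import DomainError
from .model import (
    AccessMode,
    DatasetAssessmentRecord,
    IdentifyingElement,
    LicenceStatus,
    LinkUpdateMode,
    ProcessDocumentation,
    RichMetadataElements,
    StructureStatus,
    SurveyTable,
    Tristate,
    VocabularyPractice,
)

N_CRITERIA = 12
CRITERIA = ("f1", "f2", "f3", "a1", "a2",
            "i1", "i2", "i3", "i4", "r1", "r2", "r3")

#: the vocabulary practices considered comprehensible to a naive user
COMPREHENSIBLE_VOCABULARY = frozenset({
    VocabularyPractice.STANDARD,
    VocabularyPractice.RETRIEVABLE_GLOSSARY,
    VocabularyPractice.COLLABORATIVE,
})

#: checklist of elements identifying a dataset (or metadata) through time;
#: configurable because the minimal triple is a catalogue-practice choice
DEFAULT_ELEMENT_CHECKLIST = frozenset(IdentifyingElement)


class CriterionStatus(str, enum.Enum):
    FULFILLED = "fulfilled"
    PARTIAL = "partial"
    NOT_FULFILLED = "not_fulfilled"


@dataclass(frozen=True)
class FairScore:
    """Per-criterion scores, per-principle subtotals and the total."""

    dataset_id: str
    f1: float
    f2: float
    f3: float
    a1: int
    a2: int
    i1: int
    i2: int
    i3: int
    i4: int
    r1: float
    r2: float
    r3: float

    @property
    def findable_subtotal(self) -> float:
        return self.f1 + self.f2 + self.f3

    @property
    def accessible_subtotal(self) -> float:
        return self.a1 + self.a2

    @property
    def interoperable_subtotal(self) -> float:
        return self.i1 + self.i2 + self.i3 + self.i4

    @property
    def reusable_subtotal(self) -> float:
        return self.r1 + self.r2 + self.r3

    @property
    def total(self) -> float:
        return (self.findable_subtotal + self.accessible_subtotal
                + self.interoperable_subtotal + self.reusable_subtotal)

    @property
    def criteria_fulfilled(self) -> int:
        return sum(1 for c in CRITERIA if getattr(self, c) == 1)

    def as_dict(self) -> dict:
        d = {"dataset_id": self.dataset_id}
        d.update({c: getattr(self, c) for c in CRITERIA})
        d.update({
            "findable_subtotal": self.findable_subtotal,
            "accessible_subtotal": self.accessible_subtotal,
            "interoperable_subtotal": self.interoperable_subtotal,
            "reusable_subtotal": self.reusable_subtotal,
            "total": self.total,
            "criteria_fulfilled": self.criteria_fulfilled,
        })
        return d


def _identifiability(identifier_present: bool,
                     elements: frozenset | set,
                     checklist: frozenset) -> float:
    """Shared F1/F2 scale: 1 if a unique identifier exists or the full
    element checklist is available; 0.5 if exactly one element is missing
    (and no identifier); else 0."""
    if identifier_present or checklist <= set(elements):
        return 1.0
    if len(checklist - set(elements)) == 1:
        return 0.5
    return 0.0


def score_findable(record: DatasetAssessmentRecord,
                   checklist: frozenset = DEFAULT_ELEMENT_CHECKLIST
                   ) -> tuple[float, float, float]:
    """F1 (identifiable data), F2 (identifiable metadata), F3 (link)."""
    ident = record.identification
    f1 = _identifiability(ident.data_identifier_present,
                          ident.data_identifying_elements, checklist)
    f2 = _identifiability(ident.metadata_identifier_present,
                          ident.metadata_identifying_elements, checklist)
    mi = record.metadata_info
    if mi.metadata_exist != Tristate.YES:
        f3 = 0.0
    elif mi.link_update_mode == LinkUpdateMode.AUTOMATIC:
        f3 = 1.0
    elif mi.link_update_mode == LinkUpdateMode.MANUAL:
        f3 = 0.5
    else:
        f3 = 0.0
    return f1, f2, f3


def score_accessible(record: DatasetAssessmentRecord) -> tuple[int, int]:
    """A1 (data access protocol/URL), A2 (metadata access protocol/URL)."""
    documented = (AccessMode.DOCUMENTED_PROTOCOL, AccessMode.URL)
    a1 = 1 if record.data_access_mode in documented else 0
    a2 = 1 if record.metadata_info.access_mode in documented else 0
    return a1, a2


def score_interoperable(record: DatasetAssessmentRecord
                        ) -> tuple[int, int, int, int]:
    """I1-I4: documented structures and comprehensible vocabularies for
    data and metadata."""
    i1 = 1 if record.data_structure_documented == Tristate.YES else 0
    i2 = 1 if record.data_vocabulary_practice in COMPREHENSIBLE_VOCABULARY else 0
    mi = record.metadata_info
    i3 = 1 if mi.structure_status in (StructureStatus.STANDARD_SCHEMA,
                                      StructureStatus.DOCUMENTED) else 0
    i4 = 1 if mi.vocabulary_practice in COMPREHENSIBLE_VOCABULARY else 0
    return i1, i2, i3, i4


_R1 = {RichMetadataElements.ALL_AVAILABLE: 1.0,
       RichMetadataElements.ONE_MISSING: 0.5,
       RichMetadataElements.MORE_MISSING: 0.0}
_R2 = {ProcessDocumentation.FULL: 1.0,
       ProcessDocumentation.PARTIAL: 0.5,
       ProcessDocumentation.NONE: 0.0}
_R3 = {LicenceStatus.DATA_AND_METADATA: 1.0,
       LicenceStatus.DATA_ONLY: 0.5,
       LicenceStatus.NONE: 0.0}


def score_reusable(record: DatasetAssessmentRecord
                   ) -> tuple[float, float, float]:
    """R1 (rich-description elements), R2 (process documentation),
    R3 (licensing)."""
    reus = record.reusability
    return (_R1[reus.rich_metadata_elements],
            _R2[reus.process_documentation],
            _R3[reus.licence_status])


def score_fair(record: DatasetAssessmentRecord,
               checklist: frozenset = DEFAULT_ELEMENT_CHECKLIST) -> FairScore:
    """Apply the full 12-criterion rubric to one record."""
    f1, f2, f3 = score_findable(record, checklist)
    a1, a2 = score_accessible(record)
    i1, i2, i3, i4 = score_interoperable(record)
    r1, r2, r3 = score_reusable(record)
    return FairScore(dataset_id=record.dataset_id,
                     f1=f1, f2=f2, f3=f3, a1=a1, a2=a2,
                     i1=i1, i2=i2, i3=i3, i4=i4, r1=r1, r2=r2, r3=r3)


def score_cohort_fair(table: SurveyTable,
                      checklist: frozenset = DEFAULT_ELEMENT_CHECKLIST
                      ) -> list[FairScore]:
    """Score every record of a (merged, one-row-per-dataset) table."""
    return [score_fair(rec, checklist) for rec in table.records]


def criterion_status(score: float) -> CriterionStatus:
    """Map a criterion score to fulfilled (1) / partial (0.5) /
    not_fulfilled (0); anything else is a domain error."""
    if score == 1:
        return CriterionStatus.FULFILLED
    if score == 0.5:
        return CriterionStatus.PARTIAL
    if score == 0:
        return CriterionStatus.NOT_FULFILLED
    raise DomainError(f"criterion score must be in {{0, 0.5, 1}}, got {score}")


def scores_to_frame(scores: Iterable[FairScore]):
    """FairScores as a pandas DataFrame, one row per dataset."""
    import pandas as pd

    return pd.DataFrame([s.as_dict() for s in scores])
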