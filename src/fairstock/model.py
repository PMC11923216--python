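"""Domain model for survey-derived livestock dataset descriptions.

A :class:`DatasetAssessmentRecord` captures everything the assessment
rubrics need to know about one dataset as described by one respondent in
one survey round: data-governance roles (GDPR accountability), identifier
and metadata availability (findability), access protocols (accessibility),
structure/vocabulary documentation (interoperability) and rich-description,
process-documentation and licensing status (reusability), plus the
characterisation fields used for the cohort summaries (species, content,
purposes, storage, collection practice, consent).

Field-level typing is enforced at construction (pydantic); *cross-field*
consistency rules are deliberately not enforced at construction — survey
answers are frequently inconsistent and the pipeline must be able to hold
and report them.  Use :func:`validate_record` to obtain the list of
violated rules for a record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import KeyCollisionError

__all__ = [
    "Tristate",
    "Round",
    "Species",
    "LanguageStatus",
    "ContentType",
    "Purpose",
    "CollectionSources",
    "CollectionMode",
    "StorageFormat",
    "QualityPractice",
    "IdentifyingElement",
    "LinkUpdateMode",
    "StructureStatus",
    "VocabularyPractice",
    "AccessMode",
    "RichMetadataElements",
    "ProcessDocumentation",
    "LicenceStatus",
    "ConsentConsortium",
    "GovernanceRoles",
    "IdentificationInfo",
    "MetadataInfo",
    "ReusabilityInfo",
    "DatasetAssessmentRecord",
    "AnswerQuality",
    "ProvenanceEntry",
    "SurveyTable",
    "Violation",
    "validate_record",
    "flatten_record",
    "record_from_flat",
    "FLAT_COLUMNS",
    "SET_COLUMNS",
    "BOOL_COLUMNS",
    "ENUM_COLUMNS",
    "MANDATORY_COLUMNS",
]


# --------------------------------------------------------------------------
# Enumerations
# --------------------------------------------------------------------------

class Tristate(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Round(str, enum.Enum):
    R1 = "r1"
    R2 = "r2"


class Species(str, enum.Enum):
    CATTLE = "cattle"
    SWINE = "swine"
    POULTRY = "poultry"
    SALMONIDS = "salmonids"


class LanguageStatus(str, enum.Enum):
    ENGLISH = "english"
    NOT_ENGLISH = "not_english"
    TRANSLATED = "translated"


class ContentType(str, enum.Enum):
    LABORATORY_RESULTS = "laboratory_results"
    BIOSECURITY = "biosecurity"
    PRODUCTION_RESULTS = "production_results"
    TREATMENT = "treatment"
    CLINICAL_OBSERVATION = "clinical_observation"
    ANIMAL_MOVEMENTS = "animal_movements"
    ECONOMIC = "economic"
    BEHAVIOUR = "behaviour"


class Purpose(str, enum.Enum):
    PRODUCTION_INFORMATION = "production_information"
    SURVEILLANCE = "surveillance"
    LEGISLATION = "legislation"
    LAB_ACTIVITIES = "lab_activities"
    OTHER_BUSINESS = "other_business"
    RESEARCH_INTEGRATION = "research_integration"


class CollectionSources(str, enum.Enum):
    SINGLE_SOURCE = "single_source"
    MULTIPLE_SAME_TYPE = "multiple_same_type"
    MULTIPLE_DIFFERENT_TYPE = "multiple_different_type"
    UNREPORTED = "unreported"


class CollectionMode(str, enum.Enum):
    AUTOMATED = "automated"
    MANUAL = "manual"
    UNREPORTED = "unreported"


class StorageFormat(str, enum.Enum):
    RELATIONAL_DATABASE = "relational_database"
    SPREADSHEET_COLLECTION = "spreadsheet_collection"
    SINGLE_SPREADSHEET = "single_spreadsheet"
    PDF_COLLECTION = "pdf_collection"


class QualityPractice(str, enum.Enum):
    CLOSED_FORMATS = "closed_formats"
    COLLECTOR_TRAINING = "collector_training"
    MANUAL_CHECKS = "manual_checks"
    AUTOMATED_CHECKS = "automated_checks"
    INSPECTION_VERIFICATION = "inspection_verification"
    FEEDBACK_LOOPS = "feedback_loops"
    STANDARDS_PROCEDURES = "standards_procedures"


class IdentifyingElement(str, enum.Enum):
    """Minimal triple identifying a dataset (or its metadata) through time."""

    NAME = "name"
    VERSION_OR_RELEASE_DATE = "version_or_release_date"
    RESPONSIBLE_ORGANISATION = "responsible_organisation"


class LinkUpdateMode(str, enum.Enum):
    AUTOMATIC = "automatic"
    MANUAL = "manual"
    NONE_OR_UNKNOWN = "none_or_unknown"


class StructureStatus(str, enum.Enum):
    STANDARD_SCHEMA = "standard_schema"
    DOCUMENTED = "documented"
    UNDOCUMENTED = "undocumented"


class VocabularyPractice(str, enum.Enum):
    STANDARD = "standard"
    RETRIEVABLE_GLOSSARY = "retrievable_glossary"
    COLLABORATIVE = "collaborative"
    OWNER_DEFINED = "owner_defined"
    UNKNOWN = "unknown"


class AccessMode(str, enum.Enum):
    DOCUMENTED_PROTOCOL = "documented_protocol"
    URL = "url"
    NONE = "none"


class RichMetadataElements(str, enum.Enum):
    ALL_AVAILABLE = "all_available"
    ONE_MISSING = "one_missing"
    MORE_MISSING = "more_missing"


class ProcessDocumentation(str, enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


class LicenceStatus(str, enum.Enum):
    DATA_AND_METADATA = "data_and_metadata"
    DATA_ONLY = "data_only"
    NONE = "none"


class ConsentConsortium(str, enum.Enum):
    YES = "yes"
    CONDITIONAL = "conditional"
    NO = "no"


# --------------------------------------------------------------------------
# Nested record components
# --------------------------------------------------------------------------

class GovernanceRoles(BaseModel):
    """GDPR data-governance roles: who the data are about and who answers
    for their processing, and whether those roles are written down."""

    model_config = ConfigDict(validate_assignment=True)

    data_subject_identified: Tristate = Tristate.UNKNOWN
    data_subject_documented: Tristate = Tristate.UNKNOWN
    data_controller_identified: Tristate = Tristate.UNKNOWN
    data_controller_documented: Tristate = Tristate.UNKNOWN
    data_owner_identified: Tristate = Tristate.UNKNOWN


class IdentificationInfo(BaseModel):
    """Unique-identification state of the data and of its metadata."""

    model_config = ConfigDict(validate_assignment=True)

    data_identifier_present: bool = False
    data_identifying_elements: set[IdentifyingElement] = Field(default_factory=set)
    metadata_identifier_present: bool = False
    metadata_identifying_elements: set[IdentifyingElement] = Field(default_factory=set)


class MetadataInfo(BaseModel):
    """Existence and stewardship of the dataset's metadata."""

    model_config = ConfigDict(validate_assignment=True)

    metadata_exist: Tristate = Tristate.UNKNOWN
    link_update_mode: LinkUpdateMode = LinkUpdateMode.NONE_OR_UNKNOWN
    structure_status: StructureStatus = StructureStatus.UNDOCUMENTED
    vocabulary_practice: VocabularyPractice = VocabularyPractice.UNKNOWN
    access_mode: AccessMode = AccessMode.NONE


class ReusabilityInfo(BaseModel):
    """Rich-description, process-documentation and licensing state."""

    model_config = ConfigDict(validate_assignment=True)

    rich_metadata_elements: RichMetadataElements = RichMetadataElements.MORE_MISSING
    process_documentation: ProcessDocumentation = ProcessDocumentation.NONE
    licence_status: LicenceStatus = LicenceStatus.NONE


class DatasetAssessmentRecord(BaseModel):
    """One dataset as described by one respondent in one survey round."""

    model_config = ConfigDict(validate_assignment=True)

    dataset_id: str
    round: Round = Round.R1
    respondent_id: str = ""
    respondent_is_owner: bool = False

    species: set[Species] = Field(default_factory=set)
    language_status: LanguageStatus = LanguageStatus.NOT_ENGLISH
    content_types: set[ContentType] = Field(default_factory=set)
    purposes: set[Purpose] = Field(default_factory=set)
    collection_sources: CollectionSources = CollectionSources.UNREPORTED
    collection_mode: CollectionMode = CollectionMode.UNREPORTED
    storage_format: StorageFormat = StorageFormat.SINGLE_SPREADSHEET
    quality_practices: set[QualityPractice] = Field(default_factory=set)
    contains_personal_data: Tristate = Tristate.UNKNOWN

    governance: GovernanceRoles = Field(default_factory=GovernanceRoles)
    identification: IdentificationInfo = Field(default_factory=IdentificationInfo)
    metadata_info: MetadataInfo = Field(default_factory=MetadataInfo)

    data_access_mode: AccessMode = AccessMode.NONE
    data_structure_documented: Tristate = Tristate.UNKNOWN
    data_vocabulary_practice: VocabularyPractice = VocabularyPractice.UNKNOWN
    reusability: ReusabilityInfo = Field(default_factory=ReusabilityInfo)

    consent_publication: bool = True
    consent_consortium: ConsentConsortium = ConsentConsortium.YES
    consent_repository: bool = True

    # raw free-text survey answers (pre-anonymisation); dropped by anonymize()
    free_text: dict[str, str] = Field(default_factory=dict)

    @field_validator("dataset_id")
    @classmethod
    def _non_empty_id(cls, v: str) -> str:
        if not str(v).strip():
            raise ValueError("dataset_id must be non-empty")
        return str(v)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.dataset_id, self.round.value, self.respondent_id)


# --------------------------------------------------------------------------
# Answer quality & provenance
# --------------------------------------------------------------------------

class AnswerQuality(BaseModel):
    """Completeness/coherence scores for one respondent's answer to one
    open question.  An absent answer cannot be coherent, so completeness 0
    forces coherence 0."""

    model_config = ConfigDict(validate_assignment=True)

    question_id: str
    respondent_id: str
    completeness: int = Field(ge=0, le=1)
    coherence: int = Field(ge=0, le=1)

    @field_validator("coherence")
    @classmethod
    def _absent_cannot_be_coherent(cls, v: int, info) -> int:
        if info.data.get("completeness") == 0 and v != 0:
            raise ValueError("coherence must be 0 when completeness is 0")
        return v


@dataclass(frozen=True)
class ProvenanceEntry:
    """One logged edit: which field of which record changed, and why."""

    record_key: tuple[str, str, str]
    field: str
    old: object
    new: object
    reason: str

    def to_dict(self) -> dict:
        return {
            "record_key": list(self.record_key),
            "field": self.field,
            "old": self.old,
            "new": self.new,
            "reason": self.reason,
        }


@dataclass
class SurveyTable:
    """Keyed collection of records plus answer qualities and an edit log."""

    records: list[DatasetAssessmentRecord] = field(default_factory=list)
    answer_qualities: list[AnswerQuality] = field(default_factory=list)
    provenance_log: list[ProvenanceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check_keys()

    def check_keys(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise KeyCollisionError(f"duplicate record key {rec.key}")
            seen.add(rec.key)

    @property
    def dataset_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.dataset_id not in out:
                out.append(rec.dataset_id)
        return out

    @property
    def respondent_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.respondent_id and rec.respondent_id not in out:
                out.append(rec.respondent_id)
        for aq in self.answer_qualities:
            if aq.respondent_id not in out:
                out.append(aq.respondent_id)
        return out

    def log(self, key: tuple[str, str, str], field_name: str,
            old: object, new: object, reason: str) -> None:
        self.provenance_log.append(
            ProvenanceEntry(key, field_name, old, new, reason))


# --------------------------------------------------------------------------
# Cross-field validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One violated consistency rule, as data (not an exception)."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def validate_record(record: DatasetAssessmentRecord) -> list[Violation]:
    """Check the cross-field invariants of a record.

    Returns an empty list iff the record is internally consistent.  Rules:

    * ``species`` must be non-empty;
    * a governance role cannot be documented but unidentified;
    * ``metadata_exist = no`` forces the metadata stewardship fields to
      their "absent" values (no link updates, undocumented structure, no
      access mode).
    """
    violations: list[Violation] = []
    if not record.species:
        violations.append(Violation("species", "species set must be non-empty"))

    gov = record.governance
    for role in ("data_subject", "data_controller"):
        documented = getattr(gov, f"{role}_documented")
        identified = getattr(gov, f"{role}_identified")
        if documented == Tristate.YES and identified != Tristate.YES:
            violations.append(Violation(
                f"governance.{role}_documented",
                "a role cannot be documented but unidentified"))

    mi = record.metadata_info
    if mi.metadata_exist == Tristate.NO:
        if mi.link_update_mode != LinkUpdateMode.NONE_OR_UNKNOWN:
            violations.append(Violation(
                "metadata_info.link_update_mode",
                "metadata_exist=no requires link_update_mode=none_or_unknown"))
        if mi.structure_status != StructureStatus.UNDOCUMENTED:
            violations.append(Violation(
                "metadata_info.structure_status",
                "metadata_exist=no requires structure_status=undocumented"))
        if mi.access_mode != AccessMode.NONE:
            violations.append(Violation(
                "metadata_info.access_mode",
                "metadata_exist=no requires access_mode=none"))
    return violations


# --------------------------------------------------------------------------
# Flat (tabular) representation
# --------------------------------------------------------------------------

SET_SEPARATOR = ";"

#: columns holding multi-valued (set) answers, serialised ";"-joined, sorted
SET_COLUMNS: dict[str, type[enum.Enum]] = {
    "species": Species,
    "content_types": ContentType,
    "purposes": Purpose,
    "quality_practices": QualityPractice,
    "data_identifying_elements": IdentifyingElement,
    "metadata_identifying_elements": IdentifyingElement,
}

BOOL_COLUMNS = (
    "respondent_is_owner",
    "data_identifier_present",
    "metadata_identifier_present",
    "consent_publication",
    "consent_repository",
)

#: single-valued categorical columns and their enums
ENUM_COLUMNS: dict[str, type[enum.Enum]] = {
    "round": Round,
    "language_status": LanguageStatus,
    "collection_sources": CollectionSources,
    "collection_mode": CollectionMode,
    "storage_format": StorageFormat,
    "contains_personal_data": Tristate,
    "data_subject_identified": Tristate,
    "data_subject_documented": Tristate,
    "data_controller_identified": Tristate,
    "data_controller_documented": Tristate,
    "data_owner_identified": Tristate,
    "metadata_exist": Tristate,
    "metadata_link_update_mode": LinkUpdateMode,
    "metadata_structure_status": StructureStatus,
    "metadata_vocabulary_practice": VocabularyPractice,
    "metadata_access_mode": AccessMode,
    "data_access_mode": AccessMode,
    "data_structure_documented": Tristate,
    "data_vocabulary_practice": VocabularyPractice,
    "rich_metadata_elements": RichMetadataElements,
    "process_documentation": ProcessDocumentation,
    "licence_status": LicenceStatus,
    "consent_consortium": ConsentConsortium,
}

#: (flat column, attribute path) pairs in canonical order
_FLAT_SPEC: list[tuple[str, tuple[str, ...]]] = [
    ("dataset_id", ("dataset_id",)),
    ("round", ("round",)),
    ("respondent_id", ("respondent_id",)),
    ("respondent_is_owner", ("respondent_is_owner",)),
    ("species", ("species",)),
    ("language_status", ("language_status",)),
    ("content_types", ("content_types",)),
    ("purposes", ("purposes",)),
    ("collection_sources", ("collection_sources",)),
    ("collection_mode", ("collection_mode",)),
    ("storage_format", ("storage_format",)),
    ("quality_practices", ("quality_practices",)),
    ("contains_personal_data", ("contains_personal_data",)),
    ("data_subject_identified", ("governance", "data_subject_identified")),
    ("data_subject_documented", ("governance", "data_subject_documented")),
    ("data_controller_identified", ("governance", "data_controller_identified")),
    ("data_controller_documented", ("governance", "data_controller_documented")),
    ("data_owner_identified", ("governance", "data_owner_identified")),
    ("data_identifier_present", ("identification", "data_identifier_present")),
    ("data_identifying_elements", ("identification", "data_identifying_elements")),
    ("metadata_identifier_present", ("identification", "metadata_identifier_present")),
    ("metadata_identifying_elements", ("identification", "metadata_identifying_elements")),
    ("metadata_exist", ("metadata_info", "metadata_exist")),
    ("metadata_link_update_mode", ("metadata_info", "link_update_mode")),
    ("metadata_structure_status", ("metadata_info", "structure_status")),
    ("metadata_vocabulary_practice", ("metadata_info", "vocabulary_practice")),
    ("metadata_access_mode", ("metadata_info", "access_mode")),
    ("data_access_mode", ("data_access_mode",)),
    ("data_structure_documented", ("data_structure_documented",)),
    ("data_vocabulary_practice", ("data_vocabulary_practice",)),
    ("rich_metadata_elements", ("reusability", "rich_metadata_elements")),
    ("process_documentation", ("reusability", "process_documentation")),
    ("licence_status", ("reusability", "licence_status")),
    ("consent_publication", ("consent_publication",)),
    ("consent_consortium", ("consent_consortium",)),
    ("consent_repository", ("consent_repository",)),
]

FLAT_COLUMNS: list[str] = [c for c, _ in _FLAT_SPEC]
MANDATORY_COLUMNS = ("dataset_id", "round", "respondent_id")

_PATH_BY_COLUMN = dict(_FLAT_SPEC)


def _get_path(record: DatasetAssessmentRecord, path: tuple[str, ...]):
    obj = record
    for part in path:
        obj = getattr(obj, part)
    return obj


def flatten_record(record: DatasetAssessmentRecord) -> dict[str, str]:
    """Serialise a record to a flat dict of strings (the CSV row form).

    Sets are ";"-joined in sorted order; booleans become "yes"/"no".
    Free-text answers are appended under their own column names.
    """
    row: dict[str, str] = {}
    for col, path in _FLAT_SPEC:
        value = _get_path(record, path)
        if col in SET_COLUMNS:
            row[col] = SET_SEPARATOR.join(sorted(v.value for v in value))
        elif col in BOOL_COLUMNS:
            row[col] = "yes" if value else "no"
        elif isinstance(value, enum.Enum):
            row[col] = value.value
        else:
            row[col] = str(value)
    for name, text in record.free_text.items():
        row[name] = text
    return row


def record_from_flat(row: dict[str, object]) -> DatasetAssessmentRecord:
    """Rebuild a record from a flat row (inverse of :func:`flatten_record`).

    Unrecognised columns become free-text fields.  Raises pydantic
    ``ValidationError`` for tokens outside an enum's vocabulary; callers
    wanting lenient parsing should normalise first (see ``io.read_survey``).
    """
    nested: dict[str, object] = {
        "governance": {}, "identification": {},
        "metadata_info": {}, "reusability": {},
    }
    free_text: dict[str, str] = {}
    for col, raw in row.items():
        if raw is None:
            continue
        if col not in _PATH_BY_COLUMN:
            if str(raw).strip():
                free_text[col] = str(raw)
            continue
        path = _PATH_BY_COLUMN[col]
        if col in SET_COLUMNS:
            if isinstance(raw, (set, frozenset, list, tuple)):
                value: object = set(raw)
            else:
                tokens = [t.strip() for t in str(raw).split(SET_SEPARATOR)]
                value = {t for t in tokens if t}
        elif col in BOOL_COLUMNS:
            if isinstance(raw, bool):
                value = raw
            else:
                value = str(raw).strip().lower() in ("yes", "true", "1", "y")
        else:
            value = str(raw).strip() if not isinstance(raw, enum.Enum) else raw
        if len(path) == 1:
            nested[path[0]] = value
        else:
            nested[path[0]][path[1]] = value  # type: ignore[index]
    nested["free_text"] = free_text
    return DatasetAssessmentRecord(**nested)


def records_equal(a: DatasetAssessmentRecord, b: DatasetAssessmentRecord,
                  ignore: Iterable[str] = ()) -> bool:
    """Field-wise equality on the flat representation, optionally ignoring
    some columns (e.g. the record key when comparing across rounds)."""
    fa, fb = flatten_record(a), flatten_record(b)
    skip = set(ignore)
    keys = (set(fa) | set(fb)) - skip
    return all(fa.get(k, "") == fb.get(k, "") for k in keys)
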