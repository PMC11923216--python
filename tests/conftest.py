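"""Shared fixtures and helpers for the fairstock test suite."""

from __future__ import annotations

import numpy as np
import pytest

from fairstock.model import (
    DatasetAssessmentRecord,
    IdentifyingElement,
    SurveyTable,
)
from fairstock.synthetic import generate_cohort, paper_like_config

# ---------------------------------------------------------------------------
# Cohort fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study_config():
    return paper_like_config(seed=20240217)


@pytest.fixture(scope="session")
def study_cohort(study_config) -> SurveyTable:
    """A quota-mode synthetic cohort with the study marginals."""
    return generate_cohort(study_config)


def make_record(dataset_id: str = "ds1", **overrides) -> DatasetAssessmentRecord:
    """A minimal consistent record; keyword overrides are flat-ish:
    nested models can be overridden wholesale."""
    base = dict(dataset_id=dataset_id, species={"cattle"})
    base.update(overrides)
    return DatasetAssessmentRecord(**base)


# ---------------------------------------------------------------------------
# Single-field upgrade lattice (worst -> best per field), used by the
# monotonicity suites: moving right along any chain must never decrease
# any criterion score.
# ---------------------------------------------------------------------------

#: (attribute path, ordered chain worst -> best)
UPGRADE_CHAINS: list[tuple[tuple[str, ...], list]] = [
    (("identification", "data_identifier_present"), [False, True]),
    (("identification", "metadata_identifier_present"), [False, True]),
    (("metadata_info", "metadata_exist"), ["no", "unknown", "yes"]),
    (("metadata_info", "link_update_mode"),
     ["none_or_unknown", "manual", "automatic"]),
    (("metadata_info", "structure_status"),
     ["undocumented", "documented", "standard_schema"]),
    (("metadata_info", "vocabulary_practice"),
     ["unknown", "owner_defined", "collaborative", "retrievable_glossary",
      "standard"]),
    (("metadata_info", "access_mode"), ["none", "url", "documented_protocol"]),
    (("data_access_mode",), ["none", "url", "documented_protocol"]),
    (("data_structure_documented",), ["no", "unknown", "yes"]),
    (("data_vocabulary_practice",),
     ["unknown", "owner_defined", "collaborative", "retrievable_glossary",
      "standard"]),
    (("reusability", "rich_metadata_elements"),
     ["more_missing", "one_missing", "all_available"]),
    (("reusability", "process_documentation"), ["none", "partial", "full"]),
    (("reusability", "licence_status"),
     ["none", "data_only", "data_and_metadata"]),
    (("governance", "data_subject_identified"), ["no", "unknown", "yes"]),
    (("governance", "data_subject_documented"), ["no", "unknown", "yes"]),
    (("governance", "data_controller_identified"), ["no", "unknown", "yes"]),
    (("governance", "data_controller_documented"), ["no", "unknown", "yes"]),
]

_ELEMENT_VALUES = sorted(e.value for e in IdentifyingElement)


def _get(record, path):
    obj = record
    for part in path:
        obj = getattr(obj, part)
    return obj


def _set(record, path, value):
    obj = record
    for part in path[:-1]:
        obj = getattr(obj, part)
    setattr(obj, path[-1], value)


def random_upgrade(rng: np.random.Generator,
                   record: DatasetAssessmentRecord
                   ) -> DatasetAssessmentRecord | None:
    """Return a deep copy of ``record`` upgraded by one step along one
    randomly chosen chain, or None if the chosen field is already best.

    Besides the enum chains, adding one identifying element to either
    element set also counts as an upgrade.
    """
    n_moves = len(UPGRADE_CHAINS) + 2
    choice = int(rng.integers(0, n_moves))
    upgraded = record.model_copy(deep=True)
    if choice >= len(UPGRADE_CHAINS):
        attr = ("data_identifying_elements" if choice == len(UPGRADE_CHAINS)
                else "metadata_identifying_elements")
        current = {e.value for e in getattr(upgraded.identification, attr)}
        missing = [e for e in _ELEMENT_VALUES if e not in current]
        if not missing:
            return None
        current.add(str(rng.choice(missing)))
        setattr(upgraded.identification, attr, current)
        return upgraded
    path, chain = UPGRADE_CHAINS[choice]
    value = _get(record, path)
    value = value.value if hasattr(value, "value") else value
    idx = chain.index(value)
    if idx == len(chain) - 1:
        return None
    _set(upgraded, path, chain[idx + 1])
    return upgraded


def random_record(rng: np.random.Generator) -> DatasetAssessmentRecord:
    """A record with every rubric-relevant field drawn uniformly from its
    full domain (including inconsistent combinations: the scorers must be
    total functions)."""
    def pick(options):
        return options[int(rng.integers(0, len(options)))]

    def subset(options):
        return {o for o in options if rng.random() < 0.5}

    tri = ["yes", "no", "unknown"]
    return DatasetAssessmentRecord(
        dataset_id=f"rr{rng.integers(0, 10**9)}",
        species={"swine"},
        contains_personal_data=pick(tri),
        governance=dict(
            data_subject_identified=pick(tri),
            data_subject_documented=pick(tri),
            data_controller_identified=pick(tri),
            data_controller_documented=pick(tri),
            data_owner_identified=pick(tri),
        ),
        identification=dict(
            data_identifier_present=bool(rng.integers(0, 2)),
            data_identifying_elements=subset(_ELEMENT_VALUES),
            metadata_identifier_present=bool(rng.integers(0, 2)),
            metadata_identifying_elements=subset(_ELEMENT_VALUES),
        ),
        metadata_info=dict(
            metadata_exist=pick(tri),
            link_update_mode=pick(["automatic", "manual", "none_or_unknown"]),
            structure_status=pick(["standard_schema", "documented",
                                   "undocumented"]),
            vocabulary_practice=pick(["standard", "retrievable_glossary",
                                      "collaborative", "owner_defined",
                                      "unknown"]),
            access_mode=pick(["documented_protocol", "url", "none"]),
        ),
        data_access_mode=pick(["documented_protocol", "url", "none"]),
        data_structure_documented=pick(tri),
        data_vocabulary_practice=pick(["standard", "retrievable_glossary",
                                       "collaborative", "owner_defined",
                                       "unknown"]),
        reusability=dict(
            rich_metadata_elements=pick(["all_available", "one_missing",
                                         "more_missing"]),
            process_documentation=pick(["full", "partial", "none"]),
            licence_status=pick(["data_and_metadata", "data_only", "none"]),
        ),
    )
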