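"""GDPR accountability rubric.

The GDPR applies only to datasets containing personal data.  Of its seven
data-protection principles, six concern data-management processes and are
out of scope here; the rubric assesses the minimum requirement of
*accountability*: can the data-governance roles (data subject and data
controller) be identified, and are those roles formally documented.

Two binary criteria:

* ``identified_roles`` = 1 iff both roles are identified;
* ``documented_roles`` = 1 iff both roles are documented.

An *unknown* answer never fulfils a criterion, and an unknown
personal-data status makes the rubric not applicable (with a logged
caveat) rather than silently scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .errors import ApplicabilityError
from .model import DatasetAssessmentRecord, SurveyTable, Tristate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GdprScore:
    """Accountability scores for one dataset; scores are ``None`` when the
    regulation does not apply (no personal data)."""

    dataset_id: str
    applicable: bool
    identified_roles: Optional[int] = None
    documented_roles: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.applicable:
            if self.identified_roles is not None or self.documented_roles is not None:
                raise ApplicabilityError(
                    "non-applicable GdprScore cannot carry scores")
        else:
            if self.identified_roles not in (0, 1) or self.documented_roles not in (0, 1):
                raise ValueError("criterion scores must be 0 or 1")
            if self.documented_roles == 1 and self.identified_roles != 1:
                raise ValueError(
                    "documented roles imply identified roles")

    @property
    def total(self) -> Optional[int]:
        if not self.applicable:
            return None
        return self.identified_roles + self.documented_roles

    def as_dict(self) -> dict:
        return {"dataset_id": self.dataset_id, "applicable": self.applicable,
                "identified_roles": self.identified_roles,
                "documented_roles": self.documented_roles,
                "total": self.total}


def gdpr_applicable(record: DatasetAssessmentRecord) -> bool:
    """True iff the record declares personal data.  An unknown status is
    treated as not applicable, with a logged caveat (the real status may
    differ and the respondent simply did not know)."""
    status = record.contains_personal_data
    if status == Tristate.UNKNOWN:
        logger.warning(
            "dataset %s: personal-data status unknown; GDPR accountability "
            "not assessed (caveat: applicability could not be established)",
            record.dataset_id)
        return False
    return status == Tristate.YES


def score_gdpr(record: DatasetAssessmentRecord) -> GdprScore:
    """Score the two accountability criteria for a personal-data record.

    Raises
    ------
    ApplicabilityError : the record does not contain personal data.
    """
    if not gdpr_applicable(record):
        raise ApplicabilityError(
            f"dataset {record.dataset_id}: GDPR accountability is only "
            "assessed for datasets containing personal data")
    gov = record.governance
    identified = int(gov.data_subject_identified == Tristate.YES
                     and gov.data_controller_identified == Tristate.YES)
    documented = int(gov.data_subject_documented == Tristate.YES
                     and gov.data_controller_documented == Tristate.YES)
    # an undocumented-but-unidentified role cannot count as documented
    documented = min(documented, identified)
    return GdprScore(dataset_id=record.dataset_id, applicable=True,
                     identified_roles=identified, documented_roles=documented)


def score_cohort_gdpr(table: SurveyTable) -> list[GdprScore]:
    """GdprScore for every dataset; non-applicable datasets get a
    flag-only score."""
    out = []
    for rec in table.records:
        if gdpr_applicable(rec):
            out.append(score_gdpr(rec))
        else:
            out.append(GdprScore(dataset_id=rec.dataset_id, applicable=False))
    return out


def mean_score_by_role(scores: Iterable[GdprScore],
                       owner_flags: Mapping[str, bool]
                       ) -> tuple[Optional[float], Optional[float]]:
    """Mean accountability total split by who answered the survey.

    ``owner_flags`` maps dataset_id to True when the data owner (rather
    than a data user) completed the survey.  Only applicable scores enter
    the means; an empty group yields ``None``.
    """
    owner_totals: list[int] = []
    user_totals: list[int] = []
    for score in scores:
        if not score.applicable:
            continue
        if score.dataset_id not in owner_flags:
            raise KeyError(
                f"no owner flag for scored dataset {score.dataset_id}")
        (owner_totals if owner_flags[score.dataset_id]
         else user_totals).append(score.total)
    owner_mean = sum(owner_totals) / len(owner_totals) if owner_totals else None
    user_mean = sum(user_totals) / len(user_totals) if user_totals else None
    return owner_mean, user_mean
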