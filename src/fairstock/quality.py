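"""Answer-quality grading.

Each open survey answer receives two binary scores: *completeness* (was an
answer given at all) and *coherence* (was the answer consistent with the
question scope and the other information available about the dataset).
The coherence judgment itself is human input; this module only aggregates
the recorded scores.

For every question, the global quality grade is the sum of the quality
scores actually obtained across respondents divided by the maximum
obtainable (2 per respondent).  A grade strictly below 0.75 is *low*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, FairstockError
from .model import AnswerQuality, SurveyTable

logger = logging.getLogger(__name__)

LOW_QUALITY_THRESHOLD = 0.75

#: survey category for each question key (question keys are the flat
#: survey columns; prefix groups follow the survey's category labels)
CATEGORY_BY_QUESTION: dict[str, str] = {
    # A. Governance
    "contains_personal_data": "A. Governance",
    "data_subject_identified": "A. Governance",
    "data_subject_documented": "A. Governance",
    "data_controller_identified": "A. Governance",
    "data_controller_documented": "A. Governance",
    "data_owner_identified": "A. Governance",
    "consent_consortium": "A. Governance",
    "consent_repository": "A. Governance",
    # B. Management
    "collection_sources": "B. Management",
    "collection_mode": "B. Management",
    "quality_practices": "B. Management",
    "data_access_mode": "B. Management",
    "process_documentation": "B. Management",
    "licence_status": "B. Management",
    # C. Data model
    "storage_format": "C. Data model",
    "data_structure_documented": "C. Data model",
    "data_vocabulary_practice": "C. Data model",
    "data_identifier_present": "C. Data model",
    "data_identifying_elements": "C. Data model",
    # D. Description
    "species": "D. Description",
    "language_status": "D. Description",
    "content_types": "D. Description",
    "purposes": "D. Description",
    "rich_metadata_elements": "D. Description",
    # E. Metadata
    "metadata_exist": "E. Metadata",
    "metadata_identifier_present": "E. Metadata",
    "metadata_identifying_elements": "E. Metadata",
    "metadata_link_update_mode": "E. Metadata",
    "metadata_structure_status": "E. Metadata",
    "metadata_vocabulary_practice": "E. Metadata",
    "metadata_access_mode": "E. Metadata",
}

UNCATEGORISED = "Z. Uncategorised"


@dataclass(frozen=True)
class QuestionQualityGrade:
    """Aggregated quality of all answers to one question."""

    question_id: str
    obtained: int
    maximum: int
    grade: float
    is_low: bool


def grade_question(qualities: Sequence[AnswerQuality]) -> QuestionQualityGrade:
    """Global quality grade for one question.

    ``obtained`` is the summed completeness+coherence over respondents;
    ``maximum`` is 2 per respondent; ``grade = obtained / maximum``.

    Raises
    ------
    DomainError : empty collection.
    KeyError : the answers do not all share one question_id.
    """
    if not qualities:
        raise DomainError("cannot grade a question with no answers")
    question_ids = {q.question_id for q in qualities}
    if len(question_ids) > 1:
        raise KeyError(f"mixed question_ids: {sorted(question_ids)}")
    obtained = sum(q.completeness + q.coherence for q in qualities)
    maximum = 2 * len(qualities)
    grade = obtained / maximum
    return QuestionQualityGrade(
        question_id=qualities[0].question_id,
        obtained=obtained,
        maximum=maximum,
        grade=grade,
        is_low=grade < LOW_QUALITY_THRESHOLD,
    )


def classify_low(grades: Iterable[QuestionQualityGrade]
                 ) -> dict[str, list[QuestionQualityGrade]]:
    """Partition grades into ``low`` (grade strictly < 0.75) and
    ``acceptable`` (grade >= 0.75; exactly 0.75 is acceptable)."""
    partition: dict[str, list[QuestionQualityGrade]] = {
        "low": [], "acceptable": []}
    for g in grades:
        partition["low" if g.grade < LOW_QUALITY_THRESHOLD else
                  "acceptable"].append(g)
    return partition


def grade_table(table: SurveyTable) -> list[QuestionQualityGrade]:
    """Grade every question present in the table's answer qualities."""
    by_question: dict[str, list[AnswerQuality]] = {}
    for aq in table.answer_qualities:
        by_question.setdefault(aq.question_id, []).append(aq)
    return [grade_question(answers) for _, answers in
            sorted(by_question.items())]


def quality_profile(table: SurveyTable,
                    questions: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-question quality table ordered by survey category.

    Columns: question_id, category, n_answers, obtained, maximum, grade,
    is_low, prop_score2 (share of answers that are both complete and
    coherent).  Questions requested but absent from the answer qualities
    are omitted with a warning.

    Raises
    ------
    FairstockError : the table carries no answer qualities at all.
    """
    if not table.answer_qualities:
        raise FairstockError("survey table has no answer qualities")
    by_question: dict[str, list[AnswerQuality]] = {}
    for aq in table.answer_qualities:
        by_question.setdefault(aq.question_id, []).append(aq)
    if questions is not None:
        for q in questions:
            if q not in by_question:
                warnings.warn(f"question {q!r} has no answers; omitted",
                              stacklevel=2)
        by_question = {q: a for q, a in by_question.items()
                       if q in set(questions)}

    rows = []
    for question_id, answers in by_question.items():
        g = grade_question(answers)
        n2 = sum(1 for a in answers
                 if a.completeness == 1 and a.coherence == 1)
        rows.append({
            "question_id": question_id,
            "category": CATEGORY_BY_QUESTION.get(question_id, UNCATEGORISED),
            "n_answers": len(answers),
            "obtained": g.obtained,
            "maximum": g.maximum,
            "grade": g.grade,
            "is_low": g.is_low,
            "prop_score2": n2 / len(answers),
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["category", "question_id"]).reset_index(drop=True)


def respondent_coherence_sums(table: SurveyTable) -> dict[str, int]:
    """Summed coherence per respondent, used to resolve merge conflicts."""
    sums: dict[str, int] = {}
    for aq in table.answer_qualities:
        sums[aq.respondent_id] = sums.get(aq.respondent_id, 0) + aq.coherence
    return sums
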