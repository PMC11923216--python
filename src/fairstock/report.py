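"""Cohort summaries: characterisation counts, rubric breakdowns and the
integer percentages used in reporting.

Percentages are always derived through :func:`percent` (nearest integer,
halves away from zero) so that printed figures are consistent across the
package.  Species tallies count a multi-species dataset once per species,
so they may sum to more than the number of datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import CompletenessError, DomainError
from .fair import CRITERIA, FairScore, criterion_status
from .gdpr import GdprScore, mean_score_by_role
from .model import (
    ConsentConsortium,
    ContentType,
    Purpose,
    Species,
    SurveyTable,
    Tristate,
)

HALF_CRITERIA = 6  # at least half of the 12 FAIR criteria fulfilled


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded to the nearest with halves away from
    zero (so 2.5% -> 3%, matching how survey percentages are printed).

    Raises :class:`DomainError` unless 0 <= numerator <= denominator and
    denominator > 0.
    """
    if denominator <= 0:
        raise DomainError("percent() requires a positive denominator")
    if not 0 <= numerator <= denominator:
        raise DomainError(
            f"percent() requires 0 <= numerator <= denominator, "
            f"got {numerator}/{denominator}")
    # integer arithmetic: floor(100*n/d + 1/2) for non-negative n
    return (200 * numerator + denominator) // (2 * denominator)


@dataclass
class CohortSummary:
    """All count/percentage material for one assessed cohort."""

    n_datasets: int = 0
    n_respondents: int = 0
    n_datasets_considered: Optional[int] = None  # survey denominator

    species_counts: dict[str, int] = field(default_factory=dict)
    n_multi_species: int = 0
    language_counts: dict[str, int] = field(default_factory=dict)
    content_type_counts: dict[str, int] = field(default_factory=dict)
    purpose_counts: dict[str, int] = field(default_factory=dict)
    n_multiple_purposes: int = 0
    collection_source_counts: dict[str, int] = field(default_factory=dict)
    collection_mode_counts: dict[str, int] = field(default_factory=dict)
    storage_format_counts: dict[str, int] = field(default_factory=dict)
    quality_practice_counts: dict[str, int] = field(default_factory=dict)
    vocabulary_practice_counts: dict[str, int] = field(default_factory=dict)
    n_structure_documented: int = 0
    n_metadata_available: int = 0
    n_personal_data: int = 0

    fair_criterion_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    n_at_least_half_criteria: int = 0
    n_all_criteria: int = 0
    mean_fair_total: float = 0.0

    gdpr_n_applicable: int = 0
    gdpr_identified_counts: dict[str, int] = field(default_factory=dict)
    gdpr_documented_counts: dict[str, int] = field(default_factory=dict)
    gdpr_n_full_compliance: int = 0
    gdpr_owner_mean: Optional[float] = None
    gdpr_user_mean: Optional[float] = None

    consent_publication_count: int = 0
    consent_consortium_counts: dict[str, int] = field(default_factory=dict)
    consent_repository_refused: int = 0

    def percent_of_cohort(self, count: int) -> int:
        return percent(count, self.n_datasets)

    @property
    def response_rate_pct(self) -> Optional[int]:
        if self.n_datasets_considered:
            return percent(self.n_datasets, self.n_datasets_considered)
        return None

    def to_dict(self) -> dict:
        d = {
            "n_datasets": self.n_datasets,
            "n_respondents": self.n_respondents,
            "n_datasets_considered": self.n_datasets_considered,
            "response_rate_pct": self.response_rate_pct,
            "species_counts": dict(self.species_counts),
            "n_multi_species": self.n_multi_species,
            "language_counts": dict(self.language_counts),
            "content_type_counts": dict(self.content_type_counts),
            "purpose_counts": dict(self.purpose_counts),
            "n_multiple_purposes": self.n_multiple_purposes,
            "collection_source_counts": dict(self.collection_source_counts),
            "collection_mode_counts": dict(self.collection_mode_counts),
            "storage_format_counts": dict(self.storage_format_counts),
            "quality_practice_counts": dict(self.quality_practice_counts),
            "vocabulary_practice_counts": dict(self.vocabulary_practice_counts),
            "n_structure_documented": self.n_structure_documented,
            "n_metadata_available": self.n_metadata_available,
            "n_personal_data": self.n_personal_data,
            "fair_criterion_counts": {k: dict(v) for k, v in
                                      self.fair_criterion_counts.items()},
            "n_at_least_half_criteria": self.n_at_least_half_criteria,
            "n_all_criteria": self.n_all_criteria,
            "mean_fair_total": self.mean_fair_total,
            "gdpr_n_applicable": self.gdpr_n_applicable,
            "gdpr_identified_counts": dict(self.gdpr_identified_counts),
            "gdpr_documented_counts": dict(self.gdpr_documented_counts),
            "gdpr_n_full_compliance": self.gdpr_n_full_compliance,
            "gdpr_owner_mean": self.gdpr_owner_mean,
            "gdpr_user_mean": self.gdpr_user_mean,
            "consent_publication_count": self.consent_publication_count,
            "consent_consortium_counts": dict(self.consent_consortium_counts),
            "consent_repository_refused": self.consent_repository_refused,
        }
        return d


def _count_categories(values: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return counts


def summarize_cohort(table: SurveyTable,
                     fair: Iterable[FairScore],
                     gdpr: Iterable[GdprScore],
                     n_datasets_considered: Optional[int] = None
                     ) -> CohortSummary:
    """Build the full cohort summary from a merged one-row-per-dataset
    table and its FAIR/GDPR scores.

    Raises :class:`CompletenessError` if any dataset in the table lacks a
    FAIR or GDPR score.
    """
    fair = list(fair)
    gdpr = list(gdpr)
    dataset_ids = [rec.dataset_id for rec in table.records]
    for label, scored in (("FAIR", {s.dataset_id for s in fair}),
                          ("GDPR", {s.dataset_id for s in gdpr})):
        missing = [d for d in dataset_ids if d not in scored]
        if missing:
            raise CompletenessError(
                f"{label} score missing for datasets: {', '.join(missing)}")

    summary = CohortSummary(
        n_datasets=len(table.records),
        n_respondents=len(table.respondent_ids),
        n_datasets_considered=n_datasets_considered,
    )

    for sp in Species:
        summary.species_counts[sp.value] = sum(
            1 for rec in table.records if sp in rec.species)
    summary.n_multi_species = sum(
        1 for rec in table.records if len(rec.species) > 1)
    summary.language_counts = _count_categories(
        rec.language_status.value for rec in table.records)
    for ct in ContentType:
        summary.content_type_counts[ct.value] = sum(
            1 for rec in table.records if ct in rec.content_types)
    for p in Purpose:
        summary.purpose_counts[p.value] = sum(
            1 for rec in table.records if p in rec.purposes)
    summary.n_multiple_purposes = sum(
        1 for rec in table.records if len(rec.purposes) > 1)
    summary.collection_source_counts = _count_categories(
        rec.collection_sources.value for rec in table.records)
    summary.collection_mode_counts = _count_categories(
        rec.collection_mode.value for rec in table.records)
    summary.storage_format_counts = _count_categories(
        rec.storage_format.value for rec in table.records)
    practices: dict[str, int] = {}
    for rec in table.records:
        for qp in rec.quality_practices:
            practices[qp.value] = practices.get(qp.value, 0) + 1
    summary.quality_practice_counts = practices
    summary.vocabulary_practice_counts = _count_categories(
        rec.data_vocabulary_practice.value for rec in table.records)
    summary.n_structure_documented = sum(
        1 for rec in table.records
        if rec.data_structure_documented == Tristate.YES)
    summary.n_metadata_available = sum(
        1 for rec in table.records
        if rec.metadata_info.metadata_exist == Tristate.YES)
    summary.n_personal_data = sum(
        1 for rec in table.records
        if rec.contains_personal_data == Tristate.YES)

    for crit in CRITERIA:
        counts = {"fulfilled": 0, "partial": 0, "not_fulfilled": 0}
        for score in fair:
            counts[criterion_status(getattr(score, crit)).value] += 1
        summary.fair_criterion_counts[crit] = counts
    summary.n_at_least_half_criteria = sum(
        1 for s in fair if s.criteria_fulfilled >= HALF_CRITERIA)
    summary.n_all_criteria = sum(
        1 for s in fair if s.criteria_fulfilled == len(CRITERIA))
    summary.mean_fair_total = (
        sum(s.total for s in fair) / len(fair) if fair else 0.0)

    applicable = [s for s in gdpr if s.applicable]
    summary.gdpr_n_applicable = len(applicable)
    summary.gdpr_identified_counts = _count_categories(
        str(s.identified_roles) for s in applicable)
    summary.gdpr_documented_counts = _count_categories(
        str(s.documented_roles) for s in applicable)
    summary.gdpr_n_full_compliance = sum(
        1 for s in applicable if s.total == 2)
    owner_flags = {rec.dataset_id: rec.respondent_is_owner
                   for rec in table.records}
    summary.gdpr_owner_mean, summary.gdpr_user_mean = mean_score_by_role(
        applicable, owner_flags)

    summary.consent_publication_count = sum(
        1 for rec in table.records if rec.consent_publication)
    summary.consent_consortium_counts = _count_categories(
        rec.consent_consortium.value for rec in table.records)
    summary.consent_repository_refused = sum(
        1 for rec in table.records if not rec.consent_repository)
    return summary


def fair_breakdown_by_species(fair: Iterable[FairScore],
                              table: SurveyTable) -> pd.DataFrame:
    """Per-dataset FAIR totals grouped by species.

    Multi-species datasets appear once per species, flagged in the
    ``multi_species`` column.  Raises KeyError if a scored dataset has no
    record (and hence no species) in the table.
    """
    species_by_ds = {rec.dataset_id: rec.species for rec in table.records}
    rows = []
    for score in fair:
        if score.dataset_id not in species_by_ds:
            raise KeyError(f"species unknown for dataset {score.dataset_id}")
        species = species_by_ds[score.dataset_id]
        for sp in sorted(s.value for s in species):
            rows.append({
                "species": sp,
                "dataset_id": score.dataset_id,
                "total": score.total,
                "criteria_fulfilled": score.criteria_fulfilled,
                "multi_species": len(species) > 1,
            })
    df = pd.DataFrame(rows, columns=["species", "dataset_id", "total",
                                     "criteria_fulfilled", "multi_species"])
    return df.sort_values(["species", "dataset_id"]).reset_index(drop=True)


def summary_to_markdown(summary: CohortSummary) -> str:
    """Human-readable digest with one line per FAIR criterion."""
    s = summary
    lines = ["# Cohort assessment summary", ""]
    lines.append(f"- datasets assessed: {s.n_datasets}")
    if s.response_rate_pct is not None:
        lines.append(f"- survey response rate: {s.response_rate_pct}% "
                     f"({s.n_datasets} of {s.n_datasets_considered})")
    lines.append(f"- respondents: {s.n_respondents}")
    if s.n_datasets:
        for sp, count in sorted(s.species_counts.items()):
            lines.append(f"- species {sp}: n = {count} "
                         f"({s.percent_of_cohort(count)}%)")
        lines.append(f"- datasets containing personal data: "
                     f"{s.n_personal_data}")
        lines.append(f"- datasets with identified metadata: "
                     f"{s.n_metadata_available}")
    lines += ["", "## FAIR compliance (per criterion)", ""]
    for crit in CRITERIA:
        counts = s.fair_criterion_counts.get(
            crit, {"fulfilled": 0, "partial": 0, "not_fulfilled": 0})
        lines.append(
            f"- {crit.upper()}: fulfilled {counts['fulfilled']}, "
            f"partial {counts['partial']}, "
            f"not fulfilled {counts['not_fulfilled']}")
    lines += ["",
              f"- datasets fulfilling >= {HALF_CRITERIA} criteria: "
              f"{s.n_at_least_half_criteria}",
              f"- datasets fulfilling all criteria: {s.n_all_criteria}",
              "", "## GDPR accountability", "",
              f"- applicable datasets (personal data): {s.gdpr_n_applicable}",
              f"- fully compliant (both criteria): {s.gdpr_n_full_compliance}",
              f"- mean score, owner-answered: {s.gdpr_owner_mean}",
              f"- mean score, user-answered: {s.gdpr_user_mean}",
              ""]
    return "\n".join(lines)
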