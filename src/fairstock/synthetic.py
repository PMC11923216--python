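"""Seeded synthetic survey cohorts.

The study's raw survey answers are not public (no consent for deposit),
so this module generates cohorts with the same categorical structure and
the same marginal counts the analysis reports: by default 30 datasets
described by 19 respondents, with species quotas 10 swine / 9 salmonids /
9 cattle / 4 poultry (two datasets holding both swine and cattle data),
11 datasets containing personal data, 16 with identified metadata, 20 not
in English, and rubric-relevant marginals matching the published
per-criterion counts.

Two sampling modes:

* **quota mode** (default): every configured count is hit exactly; which
  dataset receives which category is randomised.  Good-practice fields are
  assigned through a shared per-dataset latent propensity plus independent
  noise (sd ``latent_noise_sd``), so datasets that do well on one rubric
  item tend to do well on others — as real data stewardship does — without
  forcing any joint count.
* **weights mode**: fields are drawn independently with probabilities
  equal to the quota proportions; counts are then binomial, which is what
  the statistical recovery tests exercise at large n.

What the generator deliberately does not emulate: free-text noise beyond
the two reclassifiable columns, respondent-level answer styles, and the
joint distribution of rubric items beyond the single latent propensity.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError
from .model import (
    AnswerQuality,
    DatasetAssessmentRecord,
    IdentifyingElement,
    SurveyTable,
    Tristate,
    flatten_record,
    record_from_flat,
    validate_record,
)
from .quality import CATEGORY_BY_QUESTION

# ---------------------------------------------------------------------------
# Default study conditions (counts out of 30 datasets unless noted)
# ---------------------------------------------------------------------------

DEFAULT_SPECIES_QUOTAS = {"swine": 10, "salmonids": 9, "cattle": 9,
                          "poultry": 4}
DEFAULT_SPECIES_OVERLAPS: list[tuple[str, str, int]] = [("swine", "cattle", 2)]

#: single-valued fields; category order is best-first where it matters
DEFAULT_FIELD_QUOTAS: dict[str, dict[str, int]] = {
    "language_status": {"english": 9, "not_english": 20, "translated": 1},
    "collection_sources": {"multiple_different_type": 6, "single_source": 11,
                           "multiple_same_type": 12, "unreported": 1},
    "collection_mode": {"automated": 18, "manual": 6, "unreported": 6},
    "storage_format": {"relational_database": 14, "spreadsheet_collection": 8,
                       "single_spreadsheet": 7, "pdf_collection": 1},
    "contains_personal_data": {"yes": 11, "no": 19},
    "consent_publication": {"yes": 30},
    "consent_consortium": {"yes": 22, "conditional": 8},
    "consent_repository": {"yes": 19, "no": 11},
    "data_owner_identified": {"yes": 25, "unknown": 5},
    # good-practice fields (latent-correlated), best category first
    "metadata_exist": {"yes": 16, "no": 14},
    "f1_state": {"full": 16, "partial": 6, "none": 8},
    "data_access_mode": {"documented_protocol": 11, "url": 11, "none": 8},
    "data_structure_documented": {"yes": 25, "no": 3, "unknown": 2},
    "data_vocabulary_practice": {"standard": 2, "retrievable_glossary": 8,
                                 "collaborative": 4, "owner_defined": 10,
                                 "unknown": 6},
    "rich_metadata_elements": {"all_available": 18, "one_missing": 5,
                               "more_missing": 7},
    "process_documentation": {"full": 10, "partial": 5, "none": 15},
    "licence_status": {"data_and_metadata": 1, "data_only": 2, "none": 27},
}

#: fields defined only for datasets with metadata (counts out of 16)
DEFAULT_METADATA_FIELD_QUOTAS: dict[str, dict[str, int]] = {
    "f2_state": {"full": 4, "partial": 3, "none": 9},
    "metadata_link_update_mode": {"automatic": 1, "manual": 1,
                                  "none_or_unknown": 14},
    "metadata_access_mode": {"documented_protocol": 4, "url": 4, "none": 8},
    "metadata_structure_status": {"standard_schema": 1, "documented": 0,
                                  "undocumented": 15},
    "metadata_vocabulary_practice": {"standard": 1, "retrievable_glossary": 0,
                                     "collaborative": 0, "owner_defined": 8,
                                     "unknown": 7},
}

#: governance state of the 11 personal-data datasets
DEFAULT_GDPR_STATE_QUOTAS = {"full": 5, "identified_only": 3,
                             "controller_unidentified": 3}

#: multi-valued fields: per-token dataset counts
DEFAULT_SUBSET_QUOTAS: dict[str, dict[str, int]] = {
    "content_types": {"laboratory_results": 16, "biosecurity": 15,
                      "production_results": 14, "treatment": 13,
                      "clinical_observation": 13, "animal_movements": 6,
                      "economic": 5, "behaviour": 3},
    "purposes": {"production_information": 17, "surveillance": 16,
                 "legislation": 11, "lab_activities": 8,
                 "other_business": 4, "research_integration": 3},
    "quality_practices": {"closed_formats": 14, "collector_training": 5,
                          "manual_checks": 5, "automated_checks": 14,
                          "inspection_verification": 4, "feedback_loops": 17,
                          "standards_procedures": 18},
}

#: fields whose assignment follows the shared good-practice latent
LATENT_FIELDS = frozenset({
    "metadata_exist", "f1_state", "data_access_mode",
    "data_structure_documented", "data_vocabulary_practice",
    "rich_metadata_elements", "process_documentation", "licence_status",
}) | frozenset(DEFAULT_METADATA_FIELD_QUOTAS)

#: per-category (P(answer given), P(coherent | given)) for answer quality
DEFAULT_QUALITY_PARAMS: dict[str, tuple[float, float]] = {
    "A. Governance": (0.97, 0.93),
    "B. Management": (0.75, 0.67),
    "C. Data model": (0.70, 0.64),
    "D. Description": (0.92, 0.87),
    "E. Metadata": (0.60, 0.58),
}

NOT_ENGLISH_LANGUAGES = ("Norwegian", "Swedish", "Dutch", "French",
                         "Spanish", "Italian", "German", "Danish")

#: tokens that read as "no answer" and must not be created by perturbation
_MISSING = {"", "unknown", "unreported", "none_or_unknown"}

#: fields safe to perturb when simulating round-1/round-2 conflicts
CONFLICT_FIELDS = ("collection_mode", "storage_format", "data_access_mode",
                   "process_documentation", "licence_status")


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic cohort generator.

    Defaults encode the study conditions; see the module docstring.
    """

    model_config = ConfigDict(validate_assignment=True)

    n_datasets: int = Field(default=30, gt=0)
    n_respondents: int = Field(default=19, gt=1)
    n_datasets_considered: int = Field(default=38, gt=0)
    seed: int = 0
    quota_mode: bool = True
    latent_noise_sd: float = Field(default=1.0, ge=0)
    owner_probability: float = Field(default=0.4, ge=0, le=1)
    missingness_rate: float = Field(default=0.0, ge=0, le=1)

    species_quotas: dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_SPECIES_QUOTAS))
    species_overlaps: list[tuple[str, str, int]] = Field(
        default_factory=lambda: list(DEFAULT_SPECIES_OVERLAPS))
    field_quotas: dict[str, dict[str, int]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_FIELD_QUOTAS.items()})
    metadata_field_quotas: dict[str, dict[str, int]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_METADATA_FIELD_QUOTAS.items()})
    gdpr_state_quotas: dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_GDPR_STATE_QUOTAS))
    subset_quotas: dict[str, dict[str, int]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SUBSET_QUOTAS.items()})

    round2_only: int = Field(default=5, ge=0)
    dual_response: int = Field(default=4, ge=0)
    conflict_field_rate: float = Field(default=0.2, ge=0, le=1)

    quality_params: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_QUALITY_PARAMS))

    @model_validator(mode="after")
    def _check_consistency(self) -> "GeneratorConfig":
        n = self.n_datasets
        if self.quota_mode:
            overlap_total = sum(c for _, _, c in self.species_overlaps)
            if sum(self.species_quotas.values()) - overlap_total != n:
                raise ConfigurationError(
                    "species quotas minus overlaps must sum to n_datasets")
            for sp1, sp2, count in self.species_overlaps:
                for sp in (sp1, sp2):
                    if self.species_quotas.get(sp, 0) < count:
                        raise ConfigurationError(
                            f"overlap {sp1}/{sp2} exceeds quota of {sp}")
            for fname, quotas in self.field_quotas.items():
                if sum(quotas.values()) != n:
                    raise ConfigurationError(
                        f"quotas for {fname!r} sum to {sum(quotas.values())}"
                        f", expected {n}")
            n_meta = self.field_quotas["metadata_exist"].get("yes", 0)
            for fname, quotas in self.metadata_field_quotas.items():
                if sum(quotas.values()) != n_meta:
                    raise ConfigurationError(
                        f"metadata quotas for {fname!r} must sum to the "
                        f"metadata_exist=yes count ({n_meta})")
            n_personal = self.field_quotas["contains_personal_data"].get(
                "yes", 0)
            if sum(self.gdpr_state_quotas.values()) != n_personal:
                raise ConfigurationError(
                    "gdpr_state_quotas must sum to the personal-data count")
            for fname, quotas in self.subset_quotas.items():
                bad = [t for t, c in quotas.items() if not 0 <= c <= n]
                if bad:
                    raise ConfigurationError(
                        f"subset quota out of range for {fname}: {bad}")
        if self.round2_only + self.dual_response > n:
            raise ConfigurationError(
                "round2_only + dual_response cannot exceed n_datasets")
        for cat, (p_ans, p_coh) in self.quality_params.items():
            if not (0 <= p_ans <= 1 and 0 <= p_coh <= 1):
                raise ConfigurationError(
                    f"quality probabilities for {cat!r} must be in [0, 1]")
        return self


def paper_like_config(seed: int = 0) -> GeneratorConfig:
    """The default configuration: a cohort with the study's marginals."""
    return GeneratorConfig(seed=seed)


# ---------------------------------------------------------------------------
# Assignment helpers
# ---------------------------------------------------------------------------

def _assign_quota(rng: np.random.Generator, quotas: dict[str, int],
                  eligible: list[int], latent: np.ndarray | None,
                  noise_sd: float) -> dict[int, str]:
    """Assign each eligible dataset a category hitting counts exactly.

    With a latent vector, datasets are ranked by latent+noise and the
    best-first category order of ``quotas`` is filled down the ranking;
    without one the order is a uniform shuffle.
    """
    if sum(quotas.values()) != len(eligible):
        raise ConfigurationError("quota counts do not match eligible set")
    if latent is not None:
        scores = {i: latent[i] + rng.normal(0.0, noise_sd) for i in eligible}
        order = sorted(eligible, key=lambda i: -scores[i])
    else:
        order = list(eligible)
        rng.shuffle(order)
    assignment: dict[int, str] = {}
    pos = 0
    for category, count in quotas.items():
        for i in order[pos:pos + count]:
            assignment[i] = category
        pos += count
    return assignment


def _draw_weighted(rng: np.random.Generator, quotas: dict[str, int],
                   eligible: list[int]) -> dict[int, str]:
    categories = list(quotas)
    total = sum(quotas.values())
    if total == 0:
        raise ConfigurationError("cannot draw from all-zero weights")
    p = np.array([quotas[c] / total for c in categories])
    draws = rng.choice(len(categories), size=len(eligible), p=p)
    return {i: categories[d] for i, d in zip(eligible, draws)}


def _assign_subset(rng: np.random.Generator, quotas: dict[str, int],
                   n: int, quota_mode: bool,
                   ensure_nonempty: bool) -> list[set[str]]:
    """Multi-valued assignment: token t goes to exactly (quota mode) or on
    average (weights mode) ``quotas[t]`` datasets.  With ``ensure_nonempty``
    a token instance is moved from a multi-token dataset to any dataset
    left empty, keeping per-token counts intact."""
    sets: list[set[str]] = [set() for _ in range(n)]
    for token, count in quotas.items():
        if quota_mode:
            chosen = rng.choice(n, size=count, replace=False)
        else:
            chosen = np.flatnonzero(rng.random(n) < count / n)
        for i in chosen:
            sets[int(i)].add(token)
    if ensure_nonempty and quota_mode:
        for i in range(n):
            if sets[i]:
                continue
            donors = [j for j in range(n) if len(sets[j]) > 1]
            if not donors:
                break
            j = int(rng.choice(donors))
            movable = [t for t in sorted(sets[j]) if t not in sets[i]]
            if movable:
                t = str(rng.choice(movable))
                sets[j].discard(t)
                sets[i].add(t)
    return sets


def _assign_species(rng: np.random.Generator, config: GeneratorConfig
                    ) -> list[set[str]]:
    n = config.n_datasets
    if not config.quota_mode:
        cats = list(config.species_quotas)
        total = sum(config.species_quotas.values())
        p = np.array([config.species_quotas[c] / total for c in cats])
        return [{cats[int(rng.choice(len(cats), p=p))]} for _ in range(n)]
    order = list(range(n))
    rng.shuffle(order)
    remaining = dict(config.species_quotas)
    sets: list[set[str]] = [set() for _ in range(n)]
    pos = 0
    for sp1, sp2, count in config.species_overlaps:
        for i in order[pos:pos + count]:
            sets[i] = {sp1, sp2}
            remaining[sp1] -= 1
            remaining[sp2] -= 1
        pos += count
    for sp, count in remaining.items():
        for i in order[pos:pos + count]:
            sets[i] = {sp}
        pos += count
    return sets


_ALL_ELEMENTS = sorted(e.value for e in IdentifyingElement)


def _identification_fields(rng: np.random.Generator, state: str
                           ) -> tuple[bool, set[str]]:
    """Materialise an identifiability state as identifier flag + elements."""
    if state == "full":
        return True, set(_ALL_ELEMENTS)
    if state == "partial":
        dropped = str(rng.choice(_ALL_ELEMENTS))
        return False, {e for e in _ALL_ELEMENTS if e != dropped}
    n_elem = int(rng.integers(0, 2))  # 0 or 1 element
    return False, set(rng.choice(_ALL_ELEMENTS, size=n_elem, replace=False))


def _governance_fields(state: str) -> dict[str, str]:
    if state == "full":
        return {"data_subject_identified": "yes",
                "data_subject_documented": "yes",
                "data_controller_identified": "yes",
                "data_controller_documented": "yes"}
    if state == "identified_only":
        return {"data_subject_identified": "yes",
                "data_subject_documented": "yes",
                "data_controller_identified": "yes",
                "data_controller_documented": "no"}
    if state == "controller_unidentified":
        return {"data_subject_identified": "yes",
                "data_subject_documented": "unknown",
                "data_controller_identified": "no",
                "data_controller_documented": "no"}
    raise ConfigurationError(f"unknown gdpr state {state!r}")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _generate(config: GeneratorConfig) -> tuple[SurveyTable, dict]:
    """Build the post-harmonisation ("truth") cohort plus the round plan
    used by :func:`generate_rounds`."""
    rng = np.random.default_rng(config.seed)
    n = config.n_datasets

    respondents = [f"ORIG_RESP_{j:02d}" for j in range(config.n_respondents)]
    dataset_keys = [f"ORIG_DS_{i:03d}" for i in range(n)]

    # 1. answer qualities (needed before respondent pairing)
    qualities: list[AnswerQuality] = []
    coherence_sum = {r: 0 for r in respondents}
    for question, category in sorted(CATEGORY_BY_QUESTION.items()):
        p_ans, p_coh = config.quality_params.get(category, (0.8, 0.8))
        for resp in respondents:
            completeness = int(rng.random() < p_ans)
            coherence = int(completeness and rng.random() < p_coh)
            qualities.append(AnswerQuality(
                question_id=question, respondent_id=resp,
                completeness=completeness, coherence=coherence))
            coherence_sum[resp] += coherence

    # 2. per-dataset latent good-practice propensity
    latent = rng.standard_normal(n)

    species_sets = _assign_species(rng, config)

    assignments: dict[str, dict[int, str]] = {}
    all_idx = list(range(n))
    for fname, quotas in config.field_quotas.items():
        latent_vec = latent if fname in LATENT_FIELDS else None
        if config.quota_mode:
            assignments[fname] = _assign_quota(
                rng, quotas, all_idx, latent_vec, config.latent_noise_sd)
        else:
            assignments[fname] = _draw_weighted(rng, quotas, all_idx)

    meta_yes = [i for i in all_idx
                if assignments["metadata_exist"][i] == "yes"]
    for fname, quotas in config.metadata_field_quotas.items():
        if config.quota_mode:
            assignments[fname] = _assign_quota(
                rng, quotas, meta_yes, latent, config.latent_noise_sd)
        else:
            assignments[fname] = _draw_weighted(rng, quotas, meta_yes)

    personal = [i for i in all_idx
                if assignments["contains_personal_data"][i] == "yes"]
    if config.quota_mode:
        gdpr_states = _assign_quota(rng, config.gdpr_state_quotas, personal,
                                    latent, config.latent_noise_sd)
    else:
        gdpr_states = _draw_weighted(rng, config.gdpr_state_quotas, personal)

    subsets = {
        fname: _assign_subset(rng, quotas, n, config.quota_mode,
                              ensure_nonempty=fname in ("content_types",
                                                        "purposes"))
        for fname, quotas in config.subset_quotas.items()}

    # 3. round plan and respondent assignment
    order = list(range(n))
    rng.shuffle(order)
    r2_only = set(order[:config.round2_only])
    dual = set(order[config.round2_only:
                     config.round2_only + config.dual_response])
    resp_order = list(respondents)
    rng.shuffle(resp_order)
    resp_of = {i: resp_order[i % len(resp_order)] for i in range(n)}
    dual_partner: dict[int, str] = {}
    for i in sorted(dual):
        others = [r for r in respondents if r != resp_of[i]]
        partner = str(rng.choice(others))
        # the round-2 (kept) answer comes from the more coherent respondent
        if coherence_sum[partner] > coherence_sum[resp_of[i]]:
            resp_of[i], partner = partner, resp_of[i]
        dual_partner[i] = partner

    # 4. build the records
    records = []
    for i in range(n):
        state_f1 = assignments["f1_state"][i]
        ident_flag, elements = _identification_fields(rng, state_f1)
        has_meta = assignments["metadata_exist"][i] == "yes"
        row: dict[str, object] = {
            "dataset_id": dataset_keys[i],
            "round": "r2" if (i in r2_only or i in dual) else "r1",
            "respondent_id": resp_of[i],
            "respondent_is_owner":
                bool(rng.random() < config.owner_probability),
            "species": species_sets[i],
            "language_status": assignments["language_status"][i],
            "content_types": subsets["content_types"][i],
            "purposes": subsets["purposes"][i],
            "collection_sources": assignments["collection_sources"][i],
            "collection_mode": assignments["collection_mode"][i],
            "storage_format": assignments["storage_format"][i],
            "quality_practices": subsets["quality_practices"][i],
            "contains_personal_data":
                assignments["contains_personal_data"][i],
            "data_owner_identified": assignments["data_owner_identified"][i],
            "data_identifier_present": ident_flag,
            "data_identifying_elements": elements,
            "metadata_exist": assignments["metadata_exist"][i],
            "data_access_mode": assignments["data_access_mode"][i],
            "data_structure_documented":
                assignments["data_structure_documented"][i],
            "data_vocabulary_practice":
                assignments["data_vocabulary_practice"][i],
            "rich_metadata_elements":
                assignments["rich_metadata_elements"][i],
            "process_documentation": assignments["process_documentation"][i],
            "licence_status": assignments["licence_status"][i],
            "consent_publication": assignments["consent_publication"][i],
            "consent_consortium": assignments["consent_consortium"][i],
            "consent_repository": assignments["consent_repository"][i],
        }
        if has_meta and i in assignments["f2_state"]:
            m_flag, m_elements = _identification_fields(
                rng, assignments["f2_state"][i])
            row.update({
                "metadata_identifier_present": m_flag,
                "metadata_identifying_elements": m_elements,
                "metadata_link_update_mode":
                    assignments["metadata_link_update_mode"][i],
                "metadata_structure_status":
                    assignments["metadata_structure_status"][i],
                "metadata_vocabulary_practice":
                    assignments["metadata_vocabulary_practice"][i],
                "metadata_access_mode":
                    assignments["metadata_access_mode"][i],
            })
        else:
            row.update({
                "metadata_identifier_present": False,
                "metadata_identifying_elements": set(),
                "metadata_link_update_mode": "none_or_unknown",
                "metadata_structure_status": "undocumented",
                "metadata_vocabulary_practice": "unknown",
                "metadata_access_mode": "none",
            })
        if i in gdpr_states:
            row.update(_governance_fields(gdpr_states[i]))
        else:
            row.update({"data_subject_identified": "unknown",
                        "data_subject_documented": "unknown",
                        "data_controller_identified": "unknown",
                        "data_controller_documented": "unknown"})
        # raw free-text columns the anonymiser must strip
        lang = row["language_status"]
        if lang == "english":
            row["language"] = "English"
        elif lang == "translated":
            row["language"] = "Translated from " + str(
                rng.choice(NOT_ENGLISH_LANGUAGES))
        else:
            row["language"] = str(rng.choice(NOT_ENGLISH_LANGUAGES))
        if row["data_owner_identified"] == "yes":
            row["data_owner_name"] = f"ORIG_OWNER_{i:03d}"

        if not config.quota_mode and config.missingness_rate > 0:
            for fname in ("contains_personal_data",
                          "data_structure_documented", "metadata_exist"):
                if rng.random() < config.missingness_rate:
                    row[fname] = "unknown"
                    if fname == "metadata_exist":
                        row.update({
                            "metadata_link_update_mode": "none_or_unknown",
                            "metadata_structure_status": "undocumented",
                            "metadata_vocabulary_practice": "unknown",
                            "metadata_access_mode": "none"})

        record = record_from_flat(row)
        violations = validate_record(record)
        if violations:  # pragma: no cover - generator self-check
            raise ConfigurationError(
                f"generated record {record.dataset_id} violates invariants: "
                f"{[str(v) for v in violations]}")
        records.append(record)

    table = SurveyTable(records=records, answer_qualities=qualities)
    plan = {"r2_only": r2_only, "dual": dual, "dual_partner": dual_partner,
            "coherence_sum": coherence_sum}
    return table, plan


def generate_cohort(config: GeneratorConfig) -> SurveyTable:
    """Generate the harmonised synthetic cohort (one record per dataset).

    Deterministic for a given config (including its seed); in quota mode
    every configured count is reproduced exactly.
    """
    table, _ = _generate(config)
    return table


def generate_rounds(config: GeneratorConfig
                    ) -> tuple[SurveyTable, SurveyTable, SurveyTable]:
    """Generate round-1 and round-2 survey tables whose merge reproduces
    the cohort of :func:`generate_cohort` exactly.

    Round 2 re-answers ``dual_response`` datasets through a second,
    less-coherent respondent in round 1, with a fraction of fields
    perturbed to simulate the conflicts the merge has to resolve; the
    round-2 answer is the one the merge keeps (higher coherence or tie).

    Returns ``(round1, round2, truth)``.
    """
    truth, plan = _generate(config)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed) % (2 ** 31), 7]))

    r1 = SurveyTable()
    r2 = SurveyTable()
    for i, rec in enumerate(truth.records):
        if i in plan["r2_only"]:
            r2.records.append(rec.model_copy(deep=True))
        elif i in plan["dual"]:
            r2.records.append(rec.model_copy(deep=True))
            flat = flatten_record(rec)
            flat["round"] = "r1"
            flat["respondent_id"] = plan["dual_partner"][i]
            for fname in CONFLICT_FIELDS:
                current = str(flat.get(fname, ""))
                if current in _MISSING:
                    continue
                if rng.random() < config.conflict_field_rate:
                    options = [c for c in config.field_quotas[fname]
                               if c != current and c not in _MISSING]
                    if options:
                        flat[fname] = str(rng.choice(options))
            r1.records.append(record_from_flat(flat))
        else:
            r1.records.append(rec.model_copy(deep=True))

    r1_respondents = {rec.respondent_id for rec in r1.records}
    r2_respondents = {rec.respondent_id for rec in r2.records}
    for aq in truth.answer_qualities:
        if aq.respondent_id in r1_respondents:
            r1.answer_qualities.append(aq.model_copy())
        if aq.respondent_id in r2_respondents:
            r2.answer_qualities.append(aq.model_copy())
    r1.check_keys()
    r2.check_keys()
    return r1, r2, truth
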