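"""Synthetic cohort generator: quota exactness, determinism, statistical
recovery of configured marginals, and the round structure."""

from __future__ import annotations

import math

import pytest

from fairstock.errors import ConfigurationError
from fairstock.gdpr import gdpr_applicable
from fairstock.harmonize import merge_rounds
from fairstock.model import Species, Tristate, records_equal, validate_record
from fairstock.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_rounds,
    paper_like_config,
)


class TestQuotaMode:
    def test_species_quotas_hit_exactly(self, study_cohort, study_config):
        counts = {sp: sum(1 for r in study_cohort.records
                          if Species(sp) in r.species)
                  for sp in study_config.species_quotas}
        assert counts == study_config.species_quotas
        overlap = sum(1 for r in study_cohort.records
                      if {"swine", "cattle"} <= {s.value for s in r.species})
        assert overlap == 2

    def test_headline_counts_hit_exactly(self, study_cohort):
        records = study_cohort.records
        assert len(records) == 30
        assert len(study_cohort.respondent_ids) == 19
        assert sum(1 for r in records
                   if r.contains_personal_data == Tristate.YES) == 11
        assert sum(1 for r in records
                   if r.metadata_info.metadata_exist == Tristate.YES) == 16
        assert sum(1 for r in records
                   if r.language_status.value == "not_english") == 20

    def test_all_records_satisfy_invariants(self, study_cohort):
        for rec in study_cohort.records:
            assert validate_record(rec) == []

    def test_same_config_and_seed_twice_identical(self, study_config):
        a = generate_cohort(study_config)
        b = generate_cohort(study_config)
        assert all(records_equal(x, y)
                   for x, y in zip(a.records, b.records))
        assert [q.model_dump() for q in a.answer_qualities] == \
               [q.model_dump() for q in b.answer_qualities]

    def test_seed_changes_assignments_but_not_quotas(self):
        a = generate_cohort(paper_like_config(seed=1))
        b = generate_cohort(paper_like_config(seed=2))
        assert any(not records_equal(x, y)
                   for x, y in zip(a.records, b.records))
        for cohort in (a, b):
            assert sum(1 for r in cohort.records
                       if r.contains_personal_data == Tristate.YES) == 11

    def test_zero_personal_data_prevalence_disables_gdpr(self):
        config = paper_like_config(seed=4)
        config.field_quotas["contains_personal_data"] = {"yes": 0, "no": 30}
        config.gdpr_state_quotas = {}
        cohort = generate_cohort(GeneratorConfig(**config.model_dump()))
        assert not any(gdpr_applicable(r) for r in cohort.records)


class TestWeightsMode:
    def test_marginal_recovered_within_three_se(self):
        n = 10_000
        config = GeneratorConfig(n_datasets=n, quota_mode=False, seed=99,
                                 round2_only=0, dual_response=0)
        cohort = generate_cohort(config)
        p = 16 / 30  # configured metadata-exist proportion
        se = math.sqrt(p * (1 - p) / n)
        observed = sum(1 for r in cohort.records
                       if r.metadata_info.metadata_exist == Tristate.YES) / n
        assert abs(observed - p) <= 3 * se

        p_personal = 11 / 30
        se_p = math.sqrt(p_personal * (1 - p_personal) / n)
        obs_p = sum(1 for r in cohort.records
                    if r.contains_personal_data == Tristate.YES) / n
        assert abs(obs_p - p_personal) <= 3 * se_p

    def test_records_remain_consistent(self):
        config = GeneratorConfig(n_datasets=300, quota_mode=False, seed=7,
                                 missingness_rate=0.1,
                                 round2_only=0, dual_response=0)
        cohort = generate_cohort(config)
        for rec in cohort.records:
            assert validate_record(rec) == []


class TestRoundStructure:
    def test_merge_of_generated_rounds_reproduces_cohort(self, study_config):
        r1, r2, truth = generate_rounds(study_config)
        merged = merge_rounds(r1, r2)
        by_id = {r.dataset_id: r for r in merged.records}
        assert len(by_id) == len(truth.records)
        for rec in truth.records:
            assert records_equal(rec, by_id[rec.dataset_id])

    def test_round_sizes_follow_plan(self, study_config):
        r1, r2, _ = generate_rounds(study_config)
        assert len(r2.records) == (study_config.round2_only
                                   + study_config.dual_response)
        assert len(r1.records) == (study_config.n_datasets
                                   - study_config.round2_only)

    def test_dual_datasets_use_two_respondents(self, study_config):
        r1, r2, _ = generate_rounds(study_config)
        r1_by_ds = {r.dataset_id: r for r in r1.records}
        dual = [r for r in r2.records if r.dataset_id in r1_by_ds]
        assert len(dual) == study_config.dual_response
        for rec in dual:
            assert rec.respondent_id != r1_by_ds[rec.dataset_id].respondent_id


class TestConfigValidation:
    def test_species_quota_mismatch_rejected(self):
        with pytest.raises((ConfigurationError, ValueError)):
            GeneratorConfig(species_quotas={"swine": 5, "cattle": 5,
                                            "salmonids": 5, "poultry": 5},
                            species_overlaps=[])

    def test_field_quota_sum_mismatch_rejected(self):
        config = paper_like_config().model_dump()
        config["field_quotas"]["collection_mode"] = {"automated": 10,
                                                     "manual": 10,
                                                     "unreported": 5}
        with pytest.raises((ConfigurationError, ValueError)):
            GeneratorConfig(**config)

    def test_gdpr_states_must_match_personal_count(self):
        config = paper_like_config().model_dump()
        config["gdpr_state_quotas"] = {"full": 2, "identified_only": 2,
                                       "controller_unidentified": 2}
        with pytest.raises((ConfigurationError, ValueError)):
            GeneratorConfig(**config)

    def test_quality_probabilities_bounded(self):
        config = paper_like_config().model_dump()
        config["quality_params"]["E. Metadata"] = (1.4, 0.5)
        with pytest.raises((ConfigurationError, ValueError)):
            GeneratorConfig(**config)
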