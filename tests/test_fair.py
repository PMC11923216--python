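"""FAIR rubric: decision-table oracles, worked examples, monotonicity."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import make_record, random_record, random_upgrade
from fairstock.errors import DomainError
from fairstock.fair import (
    CRITERIA,
    criterion_status,
    score_accessible,
    score_fair,
    score_findable,
    score_interoperable,
    score_reusable,
)

ELEMENTS = ("name", "version_or_release_date", "responsible_organisation")
TRI = ("yes", "no", "unknown")


def _rec_meta(**meta):
    return make_record(metadata_info=meta)


class TestFindableOracle:
    def test_f1_full_enumeration(self):
        # oracle: identifier or full checklist -> 1; exactly one element
        # short of the checklist (no identifier) -> 0.5; else 0
        for flag in (False, True):
            for r in range(4):
                for combo in itertools.combinations(ELEMENTS, r):
                    rec = make_record(identification=dict(
                        data_identifier_present=flag,
                        data_identifying_elements=set(combo)))
                    expected = (1.0 if flag or len(combo) == 3
                                else 0.5 if len(combo) == 2 else 0.0)
                    assert score_findable(rec)[0] == expected, (flag, combo)

    def test_f2_mirrors_f1_on_metadata_fields(self):
        for flag in (False, True):
            for r in range(4):
                for combo in itertools.combinations(ELEMENTS, r):
                    rec = make_record(identification=dict(
                        metadata_identifier_present=flag,
                        metadata_identifying_elements=set(combo)))
                    expected = (1.0 if flag or len(combo) == 3
                                else 0.5 if len(combo) == 2 else 0.0)
                    assert score_findable(rec)[1] == expected

    def test_f3_full_enumeration(self):
        # metadata must exist for the link to count at all
        oracle = {("yes", "automatic"): 1.0, ("yes", "manual"): 0.5}
        for exist in TRI:
            for link in ("automatic", "manual", "none_or_unknown"):
                rec = _rec_meta(metadata_exist=exist, link_update_mode=link)
                assert score_findable(rec)[2] == oracle.get((exist, link), 0.0)

    def test_identifier_without_metadata_worked_example(self):
        rec = make_record(
            identification=dict(data_identifier_present=True),
            metadata_info=dict(metadata_exist="no"))
        f1, f2, f3 = score_findable(rec)
        assert (f1, f2, f3) == (1.0, 0.0, 0.0)

    def test_one_element_missing_scores_half(self):
        rec = make_record(identification=dict(
            data_identifying_elements={"name", "responsible_organisation"}))
        assert score_findable(rec)[0] == 0.5


class TestAccessibleOracle:
    @pytest.mark.parametrize("mode,expected", [
        ("documented_protocol", 1), ("url", 1), ("none", 0)])
    def test_a1_enumeration(self, mode, expected):
        assert score_accessible(make_record(data_access_mode=mode))[0] == expected

    @pytest.mark.parametrize("mode,expected", [
        ("documented_protocol", 1), ("url", 1), ("none", 0)])
    def test_a2_enumeration(self, mode, expected):
        rec = _rec_meta(metadata_exist="yes", access_mode=mode)
        assert score_accessible(rec)[1] == expected


class TestInteroperableOracle:
    def test_i1_enumeration(self):
        for tri in TRI:
            rec = make_record(data_structure_documented=tri)
            assert score_interoperable(rec)[0] == (1 if tri == "yes" else 0)

    @pytest.mark.parametrize("vocab,expected", [
        ("standard", 1), ("retrievable_glossary", 1), ("collaborative", 1),
        ("owner_defined", 0), ("unknown", 0)])
    def test_i2_and_i4_enumeration(self, vocab, expected):
        rec = make_record(data_vocabulary_practice=vocab,
                          metadata_info=dict(metadata_exist="yes",
                                             vocabulary_practice=vocab))
        scores = score_interoperable(rec)
        assert scores[1] == expected and scores[3] == expected

    @pytest.mark.parametrize("status,expected", [
        ("standard_schema", 1), ("documented", 1), ("undocumented", 0)])
    def test_i3_enumeration(self, status, expected):
        rec = _rec_meta(metadata_exist="yes", structure_status=status)
        assert score_interoperable(rec)[2] == expected


class TestReusableOracle:
    ORACLE = {
        "rich_metadata_elements": {"all_available": 1.0, "one_missing": 0.5,
                                   "more_missing": 0.0},
        "process_documentation": {"full": 1.0, "partial": 0.5, "none": 0.0},
        "licence_status": {"data_and_metadata": 1.0, "data_only": 0.5,
                           "none": 0.0},
    }

    def test_full_enumeration(self):
        for i, (field_name, table) in enumerate(self.ORACLE.items()):
            for value, expected in table.items():
                rec = make_record(reusability={field_name: value})
                assert score_reusable(rec)[i] == expected


class TestComposition:
    def test_all_best_record_scores_twelve(self):
        rec = make_record(
            identification=dict(data_identifier_present=True,
                                metadata_identifier_present=True),
            metadata_info=dict(metadata_exist="yes",
                               link_update_mode="automatic",
                               structure_status="standard_schema",
                               vocabulary_practice="standard",
                               access_mode="url"),
            data_access_mode="documented_protocol",
            data_structure_documented="yes",
            data_vocabulary_practice="standard",
            reusability=dict(rich_metadata_elements="all_available",
                             process_documentation="full",
                             licence_status="data_and_metadata"))
        score = score_fair(rec)
        assert score.total == 12 and score.criteria_fulfilled == 12

    def test_empty_record_scores_zero(self):
        score = score_fair(make_record())
        assert score.total == 0 and score.criteria_fulfilled == 0

    def test_subtotals_compose_and_sum(self, study_cohort):
        for rec in study_cohort.records:
            s = score_fair(rec)
            f1, f2, f3 = score_findable(rec)
            assert s.findable_subtotal == f1 + f2 + f3
            assert s.accessible_subtotal == sum(score_accessible(rec))
            assert s.interoperable_subtotal == sum(score_interoperable(rec))
            assert s.reusable_subtotal == sum(score_reusable(rec))
            assert s.total == sum(getattr(s, c) for c in CRITERIA)
            assert 0 <= s.total <= 12
            assert s.criteria_fulfilled == sum(
                1 for c in CRITERIA if getattr(s, c) == 1)

    def test_known_score_vector_sums(self):
        # (1,0,0,1,0,1,1,0,0,1,0.5,0) -> total 5.5, five criteria fulfilled
        vector = dict(zip(CRITERIA, (1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0.5, 0)))
        from fairstock.fair import FairScore

        score = FairScore(dataset_id="d", **vector)
        assert score.total == 5.5
        assert score.criteria_fulfilled == 5


class TestCriterionStatus:
    @pytest.mark.parametrize("value,expected", [
        (1, "fulfilled"), (0.5, "partial"), (0, "not_fulfilled")])
    def test_valid_scores(self, value, expected):
        assert criterion_status(value).value == expected

    def test_invalid_score_is_domain_error(self):
        with pytest.raises(DomainError):
            criterion_status(0.7)


def test_monotonicity_under_single_field_upgrades():
    """Upgrading any one field never decreases any criterion score."""
    rng = np.random.default_rng(1729)
    pairs = 0
    record = random_record(rng)
    while pairs < 2000:
        upgraded = random_upgrade(rng, record)
        if upgraded is None:
            record = random_record(rng)
            continue
        before, after = score_fair(record), score_fair(upgraded)
        for crit in CRITERIA:
            assert getattr(after, crit) >= getattr(before, crit), crit
        assert after.total >= before.total
        record = upgraded
        pairs += 1
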