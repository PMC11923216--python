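"""Round merging, conflict resolution, anonymisation."""

from __future__ import annotations

import pytest

from conftest import make_record
from fairstock.errors import ConfigurationError, IntegrityError
from fairstock.harmonize import (
    anonymize,
    build_denylist,
    build_id_map,
    merge_rounds,
    reclassify_field,
    scan_for_identifiers,
)
from fairstock.model import AnswerQuality, SurveyTable, records_equal


def _quality(respondent: str, coherent_answers: int) -> list[AnswerQuality]:
    """Give a respondent a controllable summed coherence."""
    return [AnswerQuality(question_id=f"q{i}", respondent_id=respondent,
                          completeness=1, coherence=1 if i < coherent_answers
                          else 0)
            for i in range(3)]


def _round(records, qualities=()) -> SurveyTable:
    return SurveyTable(records=list(records),
                       answer_qualities=list(qualities))


class TestMergeRounds:
    def test_identical_rounds_merge_to_either_with_no_log(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 storage_format="relational_database")])
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 storage_format="relational_database")])
        merged = merge_rounds(r1, r2)
        assert len(merged.records) == 1
        assert records_equal(merged.records[0], r2.records[0])
        assert merged.provenance_log == []

    def test_conflict_goes_to_more_coherent_respondent(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 collection_mode="manual")],
                    _quality("a", 2))
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 collection_mode="automated")],
                    _quality("b", 1))
        merged = merge_rounds(r1, r2)
        assert merged.records[0].collection_mode.value == "manual"
        (entry,) = merged.provenance_log
        assert entry.field == "collection_mode"
        assert entry.reason == "conflict_resolved_most_coherent"

    def test_tie_keeps_round_two_and_logs(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 collection_mode="manual")],
                    _quality("a", 2))
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 collection_mode="automated")],
                    _quality("b", 2))
        merged = merge_rounds(r1, r2)
        assert merged.records[0].collection_mode.value == "automated"
        (entry,) = merged.provenance_log
        assert entry.reason == "conflict_tie_kept_round2"

    def test_round1_fills_missing_round2_answer(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 contains_personal_data="yes")])
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 contains_personal_data="unknown")])
        merged = merge_rounds(r1, r2)
        assert merged.records[0].contains_personal_data.value == "yes"
        (entry,) = merged.provenance_log
        assert entry.reason == "round1_fills_missing"

    def test_missing_round1_answer_never_overwrites(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 contains_personal_data="unknown")])
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 contains_personal_data="no")])
        merged = merge_rounds(r1, r2)
        assert merged.records[0].contains_personal_data.value == "no"
        assert merged.provenance_log == []

    def test_dataset_only_in_one_round_passes_through(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a")])
        r2 = _round([make_record("d2", round="r2", respondent_id="b")])
        merged = merge_rounds(r1, r2)
        assert sorted(r.dataset_id for r in merged.records) == ["d1", "d2"]
        new = next(r for r in merged.records if r.dataset_id == "d2")
        assert records_equal(new, r2.records[0])

    def test_union_of_keys_and_provenance_for_every_overwrite(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 collection_mode="manual",
                                 storage_format="pdf_collection"),
                     make_record("d3", round="r1", respondent_id="a")],
                    _quality("a", 3))
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 collection_mode="automated",
                                 storage_format="relational_database"),
                     make_record("d2", round="r2", respondent_id="b")],
                    _quality("b", 0))
        merged = merge_rounds(r1, r2)
        assert {r.dataset_id for r in merged.records} == {"d1", "d2", "d3"}
        overwritten = {e.field for e in merged.provenance_log}
        assert overwritten == {"collection_mode", "storage_format"}

    def test_contradictory_rows_in_one_round_raise(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a"),
                     make_record("d1", round="r1", respondent_id="b")])
        with pytest.raises(IntegrityError):
            merge_rounds(r1, _round([]))

    def test_merge_is_idempotent(self):
        r1 = _round([make_record("d1", round="r1", respondent_id="a",
                                 collection_mode="manual")],
                    _quality("a", 2))
        r2 = _round([make_record("d1", round="r2", respondent_id="b",
                                 collection_mode="automated")],
                    _quality("b", 1))
        once = merge_rounds(r1, r2)
        again = merge_rounds(once, once)
        assert records_equal(once.records[0], again.records[0])


class TestReclassifyField:
    @pytest.mark.parametrize("raw,expected", [
        ("English", "english"),
        ("Swedish", "not_english"),
        ("  dutch  ", "not_english"),
        ("Translated from Danish", "translated"),
    ])
    def test_language_rule(self, raw, expected):
        assert reclassify_field("language", raw) == expected

    def test_empty_value_warns_and_maps_to_unknown(self):
        with pytest.warns(UserWarning):
            assert reclassify_field("language", "") == "unknown"

    def test_owner_name_collapses_to_identified_flag(self):
        assert reclassify_field("data_owner_name", "Jane Farmer") == "yes"

    def test_field_without_rule_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            reclassify_field("favourite_colour", "blue")


class TestAnonymize:
    @pytest.fixture
    def raw_table(self) -> SurveyTable:
        records = [
            make_record("FarmDB Tirol", round="r1",
                        respondent_id="alice.smith",
                        free_text={"language": "German",
                                   "data_owner_name": "A. Keller"}),
            make_record("SalmonRegistry-NO", round="r1",
                        respondent_id="bob.jones",
                        free_text={"language": "English"},
                        language_status="english"),
        ]
        qualities = _quality("alice.smith", 2) + _quality("bob.jones", 1)
        return SurveyTable(records=records, answer_qualities=qualities)

    def test_same_seed_twice_is_identical(self, raw_table):
        anon1, map1 = anonymize(raw_table, seed=11)
        anon2, map2 = anonymize(raw_table, seed=11)
        assert map1 == map2
        for a, b in zip(anon1.records, anon2.records):
            assert records_equal(a, b)

    def test_id_map_is_a_bijection_onto_1_to_n(self, raw_table):
        _, id_map = anonymize(raw_table, seed=5)
        assert sorted(id_map.dataset_ids.values()) == [1, 2]
        assert sorted(id_map.respondent_ids.values()) == [1, 2]

    def test_id_map_regenerates_from_seed(self, raw_table):
        _, id_map = anonymize(raw_table, seed=5)
        regenerated = build_id_map(list(id_map.dataset_ids),
                                   list(id_map.respondent_ids), seed=5)
        assert regenerated == id_map

    def test_denylist_scan_finds_no_original_identifier(self, raw_table):
        denylist = build_denylist(raw_table)
        assert "FarmDB Tirol" in denylist and "A. Keller" in denylist
        anon, _ = anonymize(raw_table, seed=7)
        assert scan_for_identifiers(anon, denylist) == []

    def test_language_reclassified_to_not_english(self, raw_table):
        anon, id_map = anonymize(raw_table, seed=7)
        german = next(r for r in anon.records if r.dataset_id == str(
            id_map.dataset_ids["FarmDB Tirol"]))
        assert german.language_status.value == "not_english"
        assert german.free_text == {}

    def test_owner_name_becomes_identified_owner_flag(self, raw_table):
        anon, id_map = anonymize(raw_table, seed=7)
        rec = next(r for r in anon.records if r.dataset_id == str(
            id_map.dataset_ids["FarmDB Tirol"]))
        assert rec.governance.data_owner_identified.value == "yes"

    def test_different_seeds_permute_differently_somewhere(self, raw_table):
        maps = [anonymize(raw_table, seed=s)[1].dataset_ids
                for s in range(8)]
        assert any(m != maps[0] for m in maps[1:])
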