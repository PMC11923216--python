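"""Round merging, conflict resolution and anonymisation.

Two survey rounds are harmonised into a single one-row-per-dataset table.
Datasets answered in only one round pass through; when a dataset was
answered in both rounds by different respondents, answers are aggregated
field by field: a missing answer is filled from the other round, and on a
genuine conflict the answer from the respondent with the higher summed
coherence wins (tie: the round-2 answer, it being the validation round).
Every resolution is recorded in the provenance log.

Anonymisation replaces dataset and respondent keys with random IDs drawn
as a seeded permutation (bijective, reproducible) and removes or
reclassifies identifying free-text answers, e.g. a raw language name
becomes "english"/"not_english" and a data-owner name becomes the flag
"there is an identified data owner".
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, IntegrityError
from .model import (
    DatasetAssessmentRecord,
    ProvenanceEntry,
    SurveyTable,
    Tristate,
    flatten_record,
    record_from_flat,
)
from .quality import respondent_coherence_sums

logger = logging.getLogger(__name__)

#: flat tokens that mean "no answer" for merge purposes
MISSING_TOKENS = frozenset({"", "unknown", "unreported", "none_or_unknown"})

#: columns that identify the row rather than describe the dataset
KEY_COLUMNS = frozenset({"dataset_id", "round", "respondent_id",
                         "respondent_is_owner"})


# --------------------------------------------------------------------------
# Reclassification of identifying free text
# --------------------------------------------------------------------------

def _reclassify_language(raw: str) -> str:
    clean = raw.strip().lower()
    if not clean:
        return "unknown"
    if clean == "english":
        return "english"
    if "translat" in clean:
        return "translated"
    return "not_english"


def _reclassify_owner_name(raw: str) -> str:
    # any non-empty name collapses to "there is an identified data owner"
    return "yes" if raw.strip() else "unknown"


#: rule table: free-text column -> (target description, mapping function)
RECLASSIFICATION_RULES = {
    "language": ("language_status", _reclassify_language),
    "data_owner_name": ("governance.data_owner_identified",
                        _reclassify_owner_name),
}


def reclassify_field(field_name: str, raw_value: str) -> str:
    """Deterministically map a raw free-text answer to its category.

    Empty or unmappable raw values become ``"unknown"`` with a warning.

    Raises
    ------
    ConfigurationError : no reclassification rule exists for the field.
    """
    if field_name not in RECLASSIFICATION_RULES:
        raise ConfigurationError(
            f"no reclassification rule for field {field_name!r}")
    _, func = RECLASSIFICATION_RULES[field_name]
    result = func(str(raw_value))
    if result == "unknown":
        warnings.warn(
            f"field {field_name!r}: raw value {raw_value!r} could not be "
            "reclassified; mapped to 'unknown'", stacklevel=2)
    return result


def apply_reclassification_rules(table: SurveyTable) -> None:
    """Apply every configured rule to the records' free-text answers,
    updating the corresponding categorical fields in place and logging
    each edit.  The free text itself is left for ``anonymize`` to drop."""
    for rec in table.records:
        if "language" in rec.free_text:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                new = reclassify_field("language", rec.free_text["language"])
            if new != "unknown":
                old = rec.language_status.value
                rec.language_status = new  # type: ignore[assignment]
                table.log(rec.key, "language_status", old, new,
                          "reclassified_from_free_text")
        if "data_owner_name" in rec.free_text:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                new = reclassify_field("data_owner_name",
                                       rec.free_text["data_owner_name"])
            if new == "yes" and rec.governance.data_owner_identified != Tristate.YES:
                old = rec.governance.data_owner_identified.value
                rec.governance.data_owner_identified = Tristate.YES
                table.log(rec.key, "governance.data_owner_identified",
                          old, "yes", "reclassified_from_free_text")


# --------------------------------------------------------------------------
# Round merging
# --------------------------------------------------------------------------

def _is_missing(value: str) -> bool:
    return value.strip().lower() in MISSING_TOKENS


def _one_record_per_dataset(table: SurveyTable, round_name: str
                            ) -> dict[str, DatasetAssessmentRecord]:
    by_dataset: dict[str, DatasetAssessmentRecord] = {}
    for rec in table.records:
        if rec.dataset_id in by_dataset:
            raise IntegrityError(
                f"dataset {rec.dataset_id}: contradictory rows within "
                f"round {round_name}")
        by_dataset[rec.dataset_id] = rec
    return by_dataset


def merge_rounds(round1: SurveyTable, round2: SurveyTable) -> SurveyTable:
    """Merge the two survey rounds into one record per dataset.

    See the module docstring for the aggregation and conflict rules.
    Raises :class:`IntegrityError` if a round contains more than one row
    for the same dataset.
    """
    r1_by_ds = _one_record_per_dataset(round1, "r1")
    r2_by_ds = _one_record_per_dataset(round2, "r2")

    merged = SurveyTable()
    merged.provenance_log.extend(round1.provenance_log)
    merged.provenance_log.extend(round2.provenance_log)

    seen: set[tuple[str, str]] = set()
    for aq in list(round1.answer_qualities) + list(round2.answer_qualities):
        k = (aq.question_id, aq.respondent_id)
        if k not in seen:
            seen.add(k)
            merged.answer_qualities.append(aq)
    coherence = respondent_coherence_sums(merged)

    dataset_ids = list(r1_by_ds)
    dataset_ids += [d for d in r2_by_ds if d not in r1_by_ds]

    for ds in dataset_ids:
        rec1, rec2 = r1_by_ds.get(ds), r2_by_ds.get(ds)
        if rec1 is None or rec2 is None:
            merged.records.append(copy.deepcopy(rec1 or rec2))
            continue
        flat1, flat2 = flatten_record(rec1), flatten_record(rec2)
        out = dict(flat2)  # round 2 (validation round) is the base
        for col in set(flat1) | set(flat2):
            if col in KEY_COLUMNS:
                continue
            v1, v2 = flat1.get(col, ""), flat2.get(col, "")
            if v1 == v2:
                continue
            if _is_missing(v2) and not _is_missing(v1):
                out[col] = v1
                merged.log(rec2.key, col, v2, v1, "round1_fills_missing")
            elif _is_missing(v1):
                continue
            else:
                coh1 = coherence.get(rec1.respondent_id, 0)
                coh2 = coherence.get(rec2.respondent_id, 0)
                if coh1 > coh2:
                    out[col] = v1
                    merged.log(rec2.key, col, v2, v1,
                               "conflict_resolved_most_coherent")
                else:
                    reason = ("conflict_tie_kept_round2" if coh1 == coh2
                              else "conflict_resolved_most_coherent")
                    merged.log(rec2.key, col, v1, v2, reason)
        merged.records.append(record_from_flat(out))

    merged.check_keys()
    return merged


# --------------------------------------------------------------------------
# Anonymisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IdMap:
    """Seeded bijection original key -> random integer ID, kept separately
    for datasets and respondents.  Regenerating with the same seed over the
    same key sets reproduces the mapping exactly."""

    dataset_ids: dict[str, int] = field(default_factory=dict)
    respondent_ids: dict[str, int] = field(default_factory=dict)
    seed: int = 0


def build_id_map(dataset_keys: list[str], respondent_keys: list[str],
                 seed: int) -> IdMap:
    rng = np.random.default_rng(seed)
    ds_sorted = sorted(set(dataset_keys))
    rs_sorted = sorted(set(respondent_keys))
    ds_ids = rng.permutation(len(ds_sorted)) + 1
    rs_ids = rng.permutation(len(rs_sorted)) + 1
    return IdMap(
        dataset_ids={k: int(i) for k, i in zip(ds_sorted, ds_ids)},
        respondent_ids={k: int(i) for k, i in zip(rs_sorted, rs_ids)},
        seed=seed)


def anonymize(table: SurveyTable, seed: int) -> tuple[SurveyTable, IdMap]:
    """Anonymise a survey table in two steps.

    1. Replace every dataset and respondent key with a random ID from a
       seeded permutation (1..N per entity class).
    2. Reclassify identifying free-text answers into their categorical
       flags and drop the raw text.

    Returns the anonymised table and the ID map.  The map is the only
    place where original keys survive; the table's provenance entries are
    re-keyed and any entry value containing an original identifier is
    redacted.
    """
    id_map = build_id_map([r.dataset_id for r in table.records],
                          table.respondent_ids, seed)
    denylist = build_denylist(table)

    out = SurveyTable()
    work = copy.deepcopy(table)
    apply_reclassification_rules(work)

    def _remap_key(key: tuple[str, str, str]) -> tuple[str, str, str]:
        ds, rnd, rid = key
        return (str(id_map.dataset_ids.get(ds, ds)), rnd,
                str(id_map.respondent_ids.get(rid, rid)))

    for entry in work.provenance_log:
        old, new = entry.old, entry.new
        if any(tok and tok in str(old) for tok in denylist):
            old = "<redacted>"
        if any(tok and tok in str(new) for tok in denylist):
            new = "<redacted>"
        out.provenance_log.append(ProvenanceEntry(
            _remap_key(entry.record_key), entry.field, old, new,
            entry.reason))

    for rec in work.records:
        old_key = rec.key
        rec.dataset_id = str(id_map.dataset_ids[rec.dataset_id])
        if rec.respondent_id:
            rec.respondent_id = str(id_map.respondent_ids[rec.respondent_id])
        dropped = sorted(rec.free_text)
        rec.free_text = {}
        out.records.append(rec)
        for name in dropped:
            out.provenance_log.append(ProvenanceEntry(
                rec.key, name, "<redacted>", "", "identifying_free_text_dropped"))
        logger.debug("anonymised %s -> %s", old_key, rec.key)

    for aq in work.answer_qualities:
        aq = aq.model_copy()
        aq.respondent_id = str(id_map.respondent_ids.get(
            aq.respondent_id, aq.respondent_id))
        out.answer_qualities.append(aq)

    out.check_keys()
    return out, id_map


def build_denylist(table: SurveyTable) -> set[str]:
    """Identifier strings that must not survive anonymisation: original
    dataset and respondent keys plus all free-text answer values."""
    deny: set[str] = set()
    for rec in table.records:
        deny.add(rec.dataset_id)
        if rec.respondent_id:
            deny.add(rec.respondent_id)
        deny.update(v for v in rec.free_text.values() if v.strip())
    for aq in table.answer_qualities:
        deny.add(aq.respondent_id)
    return deny


def scan_for_identifiers(table: SurveyTable, denylist: set[str]) -> list[str]:
    """Serialise the table and return every deny-listed string found in it
    (empty list = clean)."""
    payload = json.dumps(
        {"records": [flatten_record(r) for r in table.records],
         "answer_qualities": [aq.model_dump() for aq in table.answer_qualities],
         "provenance": [p.to_dict() for p in table.provenance_log]},
        default=str)
    return sorted({tok for tok in denylist if tok and tok in payload})
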