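"""Reading, writing and validating survey tables and reports.

The on-disk survey table is one row per (dataset, round, respondent) with
the flat columns documented in the shipped column dictionary
(``column_dictionary.yaml``).  CSV is UTF-8 with a header row; XLSX uses
the first sheet; JSON is a list of row objects.  Categorical tokens are
matched case-insensitively after trimming.
"""

from __future__ import annotations

import enum
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import model
from .errors import SchemaError
from .model import (
    AnswerQuality,
    CollectionMode,
    CollectionSources,
    DatasetAssessmentRecord,
    LinkUpdateMode,
    SurveyTable,
    Tristate,
    VocabularyPractice,
)

logger = logging.getLogger(__name__)

#: enums with a semantically "don't know" member used as lenient fallback
FALLBACK_MEMBER: dict[type[enum.Enum], enum.Enum] = {
    Tristate: Tristate.UNKNOWN,
    VocabularyPractice: VocabularyPractice.UNKNOWN,
    CollectionSources: CollectionSources.UNREPORTED,
    CollectionMode: CollectionMode.UNREPORTED,
    LinkUpdateMode: LinkUpdateMode.NONE_OR_UNKNOWN,
}


# --------------------------------------------------------------------------
# Column dictionary
# --------------------------------------------------------------------------

def column_dictionary() -> dict:
    """Machine-readable description of the survey-table columns.

    Built from the domain model so it can never drift from it; the same
    content is shipped as ``column_dictionary.yaml`` for survey designers.
    """
    columns: dict[str, dict] = {}
    for col in model.FLAT_COLUMNS:
        if col in model.SET_COLUMNS:
            enum_cls = model.SET_COLUMNS[col]
            columns[col] = {
                "kind": "set",
                "separator": model.SET_SEPARATOR,
                "allowed": [m.value for m in enum_cls],
            }
        elif col in model.BOOL_COLUMNS:
            columns[col] = {"kind": "flag", "allowed": ["yes", "no"]}
        elif col in model.ENUM_COLUMNS:
            enum_cls = model.ENUM_COLUMNS[col]
            columns[col] = {
                "kind": "categorical",
                "allowed": [m.value for m in enum_cls],
            }
        else:
            columns[col] = {"kind": "text"}
        if col in model.MANDATORY_COLUMNS:
            columns[col]["mandatory"] = True
    return {"columns": columns, "mandatory": list(model.MANDATORY_COLUMNS)}


def dump_column_dictionary(path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(column_dictionary(), sort_keys=False), encoding="utf-8")


def shipped_column_dictionary() -> dict:
    """The column dictionary as shipped inside the package."""
    text = resources.files("fairstock").joinpath(
        "column_dictionary.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


# --------------------------------------------------------------------------
# Survey tables
# --------------------------------------------------------------------------

def _normalise_token(col: str, token: str, table: SurveyTable,
                     key_hint: str) -> str:
    """Trim/lower-case a categorical token; map unknown tokens to the
    enum's fallback member with a logged warning, or raise SchemaError."""
    enum_cls = model.ENUM_COLUMNS[col]
    clean = token.strip().lower()
    allowed = {m.value for m in enum_cls}
    if clean in allowed:
        return clean
    fallback = FALLBACK_MEMBER.get(enum_cls)
    if fallback is not None:
        logger.warning("unknown token %r in column %r (record %s): "
                       "mapped to %r", token, col, key_hint, fallback.value)
        table.log((key_hint, "", ""), col, token, fallback.value,
                  "unknown-token-fallback")
        return fallback.value
    raise SchemaError(
        f"column {col!r}: token {token!r} not in {sorted(allowed)}")


def _rows_from_path(path: Path, fmt: str) -> list[dict]:
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return df.to_dict(orient="records")
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0, dtype=str)
        return df.fillna("").to_dict(orient="records")
    if fmt == "json":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, list):
            raise SchemaError("JSON survey table must be a list of row objects")
        return [{k: ("" if v is None else v) for k, v in row.items()}
                for row in data]
    raise SchemaError(f"unsupported survey format {fmt!r}")


def read_survey(path: str | Path, format: Optional[str] = None,
                reclassify: bool = True) -> SurveyTable:
    """Read and validate a survey table.

    Parameters
    ----------
    path : file path (CSV, XLSX or JSON).
    format : explicit format; inferred from the suffix when omitted.
    reclassify : apply the free-text reclassification rules (e.g. a raw
        ``language`` column becomes ``language_status``) and log the edits.

    Raises
    ------
    SchemaError : missing mandatory columns or invalid categorical token.
    KeyCollisionError : duplicate (dataset, round, respondent) key.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"survey file not found: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    rows = _rows_from_path(path, fmt)
    if not rows:
        raise SchemaError(f"survey file {path} contains no rows")

    header = set(rows[0])
    missing = [c for c in model.MANDATORY_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")

    table = SurveyTable()
    for row in rows:
        key_hint = str(row.get("dataset_id", "?"))
        clean_row: dict[str, object] = {}
        for col, raw in row.items():
            value = "" if raw is None else str(raw)
            if col in model.ENUM_COLUMNS and value.strip():
                clean_row[col] = _normalise_token(col, value, table, key_hint)
            elif col in model.SET_COLUMNS:
                tokens = [t.strip().lower()
                          for t in value.split(model.SET_SEPARATOR)]
                clean_row[col] = {t for t in tokens if t}
            else:
                clean_row[col] = value
        record = model.record_from_flat(clean_row)
        table.records.append(record)
    table.check_keys()

    if reclassify:
        from .harmonize import apply_reclassification_rules
        apply_reclassification_rules(table)
    return table


def write_survey(table: SurveyTable, path: str | Path,
                 format: Optional[str] = None) -> None:
    """Write a survey table (flat form) to CSV, XLSX or JSON."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    rows = [model.flatten_record(rec) for rec in table.records]
    df = pd.DataFrame(rows)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1, sort_keys=True),
                        encoding="utf-8")
    else:
        raise SchemaError(f"unsupported survey format {fmt!r}")


def read_answer_qualities(path: str | Path) -> list[AnswerQuality]:
    """Read an answer-quality table (CSV: question_id, respondent_id,
    completeness, coherence)."""
    df = pd.read_csv(path, dtype={"question_id": str, "respondent_id": str})
    required = {"question_id", "respondent_id", "completeness", "coherence"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"missing answer-quality columns: {', '.join(sorted(missing))}")
    return [AnswerQuality(question_id=r.question_id,
                          respondent_id=r.respondent_id,
                          completeness=int(r.completeness),
                          coherence=int(r.coherence))
            for r in df.itertuples(index=False)]


def write_answer_qualities(qualities: list[AnswerQuality],
                           path: str | Path) -> None:
    pd.DataFrame([q.model_dump() for q in qualities]).to_csv(path, index=False)


def write_provenance(table: SurveyTable, path: str | Path) -> None:
    """Provenance log as JSON lines, one edit per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in table.provenance_log:
            fh.write(json.dumps(entry.to_dict(), sort_keys=True,
                                default=str) + "\n")


# --------------------------------------------------------------------------
# Report writing
# --------------------------------------------------------------------------

def write_report(summary, path: str | Path, format: str = "json") -> None:
    """Write a cohort summary as JSON (round-trippable), flat CSV, or a
    human-readable markdown digest with one line per FAIR criterion."""
    from .report import summary_to_markdown

    path = Path(path)
    data = summary.to_dict()
    if format == "json":
        path.write_text(json.dumps(data, indent=1, sort_keys=True),
                        encoding="utf-8")
    elif format == "csv":
        flat = _flatten_mapping(data)
        pd.DataFrame(sorted(flat.items()),
                     columns=["key", "value"]).to_csv(path, index=False)
    elif format == "markdown":
        path.write_text(summary_to_markdown(summary), encoding="utf-8")
    else:
        raise SchemaError(f"unsupported report format {format!r}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _flatten_mapping(data: dict, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for key, value in data.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten_mapping(value, f"{full}."))
        else:
            out[full] = value
    return out
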