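"""Cohort readers/writers and eligibility filtering.

Two on-disk representations, both round-trippable field-for-field including
missing markers:

* **JSON** — one file holding a list of trial objects (one per trial), absent
  fields encoded as ``null``.
* **CSV** — a directory of flat tables joined on ``trial_id`` (mirroring how
  extraction sheets are kept): ``trials.csv`` (one row per trial: strata),
  ``versions.csv`` (one row per trial-version: design parameters),
  ``comments.csv``, ``modifications.csv`` and ``results.csv``.  Missing values
  are empty cells; nothing is imputed at read time.

Eligibility filtering applies the inclusion rules for an analysable cohort:
results available, target effect standardisable, and achieved sample size at
least the stated fraction (default 0.4) of the target.  Each excluded trial
carries exactly one primary reason, assigned by the first matching rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import ValidationError

from .model import (
    DesignParameters,
    Modification,
    OutcomeResult,
    RECComment,
    TrialRecord,
)
from .standardise import InsufficientInformationError, standardise_target

__all__ = [
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "ExclusionReason",
    "Exclusion",
    "eligibility_filter",
]

CohortFormat = Literal["csv", "json"]

VERSION_COLUMNS = (
    "trial_id",
    "version_index",
    "version_label",
    "alpha",
    "sided",
    "power",
    "allocation_ratio",
    "n_target_total",
    "n_target_evaluable",
    "attrition_rate",
    "outcome_type",
    "target_difference",
    "variability_or_control_rate",
    "elicitation_method",
)
TRIAL_COLUMNS = (
    "trial_id",
    "sponsor",
    "centres",
    "medical_field",
    "intervention_type",
    "phase",
    "comparator",
    "masking",
)
COMMENT_COLUMNS = ("trial_id", "category", "text_note", "version_raised")
MODIFICATION_COLUMNS = (
    "trial_id",
    "phase",
    "from_version",
    "to_version",
    "reason",
    "induced_by",
    "sample_size_change_fraction",
)
RESULT_COLUMNS = (
    "trial_id",
    "effect_estimate",
    "se",
    "ci_lower",
    "ci_upper",
    "sd_pooled",
    "test_statistic",
    "test_statistic_df",
    "p_value",
    "n_achieved_arm1",
    "n_achieved_arm2",
    "significant",
    "direction_matches_hypothesis",
    "source",
)

_FLOAT_FIELDS = {
    "alpha",
    "power",
    "allocation_ratio",
    "attrition_rate",
    "target_difference",
    "variability_or_control_rate",
    "sample_size_change_fraction",
    "effect_estimate",
    "se",
    "ci_lower",
    "ci_upper",
    "sd_pooled",
    "test_statistic",
    "p_value",
}
_INT_FIELDS = {
    "version_index",
    "n_target_total",
    "n_target_evaluable",
    "version_raised",
    "from_version",
    "to_version",
    "test_statistic_df",
    "n_achieved_arm1",
    "n_achieved_arm2",
}
_BOOL_FIELDS = {"significant", "direction_matches_hypothesis"}


class CohortSchemaError(Exception):
    """A cohort file violates the documented schema; names trial and field."""


def _first_error_message(trial_id: str, err: ValidationError) -> str:
    e = err.errors()[0]
    loc = ".".join(str(p) for p in e["loc"]) or "<record>"
    return f"trial {trial_id!r}: field {loc!r}: {e['msg']}"


def _coerce(field: str, raw: str) -> object:
    if raw == "":
        return None
    if field in _FLOAT_FIELDS:
        return float(raw)
    if field in _INT_FIELDS:
        return int(float(raw))
    if field in _BOOL_FIELDS:
        low = raw.strip().lower()
        if low in ("true", "1"):
            return True
        if low in ("false", "0"):
            return False
        raise ValueError(f"cannot interpret {raw!r} as a boolean")
    return raw


def _rows(df: pd.DataFrame, expected: Sequence[str], name: str) -> Iterable[dict]:
    missing_cols = set(expected) - set(df.columns)
    if missing_cols:
        raise CohortSchemaError(f"{name} is missing columns: {sorted(missing_cols)}")
    for _, row in df.iterrows():
        out: dict[str, object] = {}
        tid = str(row.get("trial_id", "<unknown>"))
        for col in expected:
            try:
                out[col] = _coerce(col, str(row[col]))
            except ValueError as exc:
                raise CohortSchemaError(f"trial {tid!r}: field {col!r}: {exc}") from exc
        yield out


def _read_table(path: Path, name: str) -> pd.DataFrame:
    fp = path / name
    if not fp.exists():
        return pd.DataFrame()
    return pd.read_csv(fp, dtype=str, keep_default_na=False)


def read_cohort(path: str | Path, format: CohortFormat = "csv") -> list[TrialRecord]:
    """Read a trial cohort, validating every record against the type invariants.

    ``path`` is a directory for the CSV layout and a file for JSON.  Absent
    fields are preserved as missing markers; trial order follows the input.
    Schema violations raise :class:`CohortSchemaError` naming the trial and
    field; unknown category labels list the allowed labels (via the
    underlying validation message).
    """
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = []
        for obj in payload:
            tid = str(obj.get("trial_id", "<unknown>"))
            try:
                records.append(TrialRecord.model_validate(obj))
            except ValidationError as exc:
                raise CohortSchemaError(_first_error_message(tid, exc)) from exc
        return records
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}; use 'csv' or 'json'")

    trials = _read_table(path, "trials.csv")
    versions = _read_table(path, "versions.csv")
    comments = _read_table(path, "comments.csv")
    modifications = _read_table(path, "modifications.csv")
    results = _read_table(path, "results.csv")

    if trials.empty:
        return []

    def _group(df: pd.DataFrame, expected: Sequence[str], name: str) -> dict[str, list[dict]]:
        grouped: dict[str, list[dict]] = {}
        if df.empty:
            return grouped
        for row in _rows(df, expected, name):
            grouped.setdefault(str(row["trial_id"]), []).append(row)
        return grouped

    versions_by = _group(versions, VERSION_COLUMNS, "versions.csv")
    comments_by = _group(comments, COMMENT_COLUMNS, "comments.csv")
    mods_by = _group(modifications, MODIFICATION_COLUMNS, "modifications.csv")
    results_by = _group(results, RESULT_COLUMNS, "results.csv")

    records: list[TrialRecord] = []
    for row in _rows(trials, TRIAL_COLUMNS, "trials.csv"):
        tid = str(row["trial_id"])
        try:
            vrows = sorted(
                versions_by.get(tid, []), key=lambda r: r["version_index"] or 0
            )
            version_objs = [
                DesignParameters(**{k: v for k, v in r.items() if k != "trial_id"})
                for r in vrows
            ]
            comment_objs = [
                RECComment(**{k: v for k, v in r.items() if k != "trial_id"})
                for r in comments_by.get(tid, [])
            ]
            mod_objs = [
                Modification(**{k: v for k, v in r.items() if k != "trial_id"})
                for r in mods_by.get(tid, [])
            ]
            result_obj: Optional[OutcomeResult] = None
            rrows = results_by.get(tid, [])
            if rrows:
                r = dict(rrows[0])
                r.pop("trial_id")
                n1, n2 = r.pop("n_achieved_arm1"), r.pop("n_achieved_arm2")
                r["n_achieved_per_arm"] = (
                    (n1, n2) if n1 is not None and n2 is not None else None
                )
                result_obj = OutcomeResult(**r)
            records.append(
                TrialRecord(
                    versions=version_objs,
                    comments=comment_objs,
                    modifications=mod_objs,
                    result=result_obj,
                    **row,
                )
            )
        except ValidationError as exc:
            raise CohortSchemaError(_first_error_message(tid, exc)) from exc
        except (TypeError, ValueError) as exc:
            raise CohortSchemaError(f"trial {tid!r}: {exc}") from exc
    return records


def _cell(value: object) -> object:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    return value


def write_cohort(
    cohort: Sequence[TrialRecord], path: str | Path, format: CohortFormat = "csv"
) -> None:
    """Write a cohort in the documented CSV-directory or JSON layout.

    Round-trips with :func:`read_cohort` field-for-field, including missing
    markers (empty cells in CSV, ``null`` in JSON).
    """
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = [t.model_dump(mode="json") for t in cohort]
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}; use 'csv' or 'json'")

    path.mkdir(parents=True, exist_ok=True)
    trial_rows, version_rows, comment_rows, mod_rows, result_rows = [], [], [], [], []
    for t in cohort:
        trial_rows.append({c: _cell(getattr(t, c)) for c in TRIAL_COLUMNS})
        for v in t.versions:
            row = {"trial_id": t.trial_id}
            row.update({c: _cell(getattr(v, c)) for c in VERSION_COLUMNS if c != "trial_id"})
            version_rows.append(row)
        for c_ in t.comments:
            row = {"trial_id": t.trial_id}
            row.update({c: _cell(getattr(c_, c)) for c in COMMENT_COLUMNS if c != "trial_id"})
            comment_rows.append(row)
        for m in t.modifications:
            row = {"trial_id": t.trial_id}
            row.update(
                {c: _cell(getattr(m, c)) for c in MODIFICATION_COLUMNS if c != "trial_id"}
            )
            mod_rows.append(row)
        if t.result is not None:
            r = t.result
            row = {"trial_id": t.trial_id}
            for c in RESULT_COLUMNS:
                if c in ("trial_id", "n_achieved_arm1", "n_achieved_arm2"):
                    continue
                row[c] = _cell(getattr(r, c))
            n = r.n_achieved_per_arm
            row["n_achieved_arm1"] = n[0] if n else ""
            row["n_achieved_arm2"] = n[1] if n else ""
            result_rows.append(row)

    for name, rows, cols in (
        ("trials.csv", trial_rows, TRIAL_COLUMNS),
        ("versions.csv", version_rows, VERSION_COLUMNS),
        ("comments.csv", comment_rows, COMMENT_COLUMNS),
        ("modifications.csv", mod_rows, MODIFICATION_COLUMNS),
        ("results.csv", result_rows, RESULT_COLUMNS),
    ):
        pd.DataFrame(rows, columns=list(cols)).to_csv(path / name, index=False)


# ---------------------------------------------------------------------------
# Eligibility


ExclusionReason = Literal[
    "no_results", "insufficient_target_es_information", "below_achieved_threshold"
]

#: Fixed order in which exclusion reasons are checked, so each trial counts once.
_REASON_ORDER: tuple[ExclusionReason, ...] = (
    "no_results",
    "insufficient_target_es_information",
    "below_achieved_threshold",
)


@dataclass(frozen=True)
class Exclusion:
    record: TrialRecord
    reason: ExclusionReason


def eligibility_filter(
    cohort: Sequence[TrialRecord], achieved_fraction_threshold: float = 0.4
) -> tuple[list[TrialRecord], list[Exclusion]]:
    """Partition a cohort into analysable trials and exclusions-with-reason.

    Reasons are assigned by the first matching rule, in order: primary-outcome
    results unavailable; insufficient information to standardise the target
    effect of the final approved protocol; achieved sample size strictly below
    ``achieved_fraction_threshold`` of the target (0.40 of 100 is included).
    """
    if not 0.0 < achieved_fraction_threshold <= 1.0:
        raise ValueError(
            f"threshold must lie in (0, 1], got {achieved_fraction_threshold}"
        )
    included: list[TrialRecord] = []
    excluded: list[Exclusion] = []
    for t in cohort:
        if t.result is None:
            excluded.append(Exclusion(t, "no_results"))
            continue
        try:
            standardise_target(t.final_approved)
        except (InsufficientInformationError, ValueError):
            excluded.append(Exclusion(t, "insufficient_target_es_information"))
            continue
        final = t.final_approved
        target_n = final.n_target_total or final.n_target_evaluable
        achieved = t.result.n_achieved_total
        if (
            target_n is not None
            and achieved is not None
            and achieved / target_n < achieved_fraction_threshold
        ):
            excluded.append(Exclusion(t, "below_achieved_threshold"))
            continue
        included.append(t)
    return included, excluded
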