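"""Cohort readers/writers. JSON-lines is the canonical on-disk format (one
patient per line); CSV is supported with a documented dialect in which the
code set and the pain observations are pipe-delimited strings.

CSV dialect:
  codes      "CPT:12345|ICD10:G89.4|..."     kind:code pairs
  pain_obs   "0:3|0:severe pain|2:5|..."     day:value pairs

Malformed rows never abort a read: they are collected into a rejects list
(and optionally a rejects file) with per-row reasons.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .records import PatientRecord, convert_pain_string, PainStringError

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _validate_record(rec: PatientRecord) -> None:
    for day, value in rec.pain_obs:
        if int(day) < 0:
            raise ValueError(f"negative day offset {day}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            convert_pain_string(value)  # raises PainStringError if unknown
        elif not 0 <= float(value) <= 10:
            raise ValueError(f"pain value {value} outside [0,10]")
    for kind in rec.codes.values():
        if kind not in ("CPT", "ICD10"):
            raise ValueError(f"unknown code kind {kind!r}")


def write_cohort(records, path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        _write_csv(records, path)
        return
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_cohort(path, rejects_path=None):
    """Read a cohort; returns ``(records, rejects)`` where rejects are
    ``(row_number, reason)`` pairs. Schema violations are reported per row
    and never silently coerced."""
    path = Path(path)
    rows = _iter_csv(path) if path.suffix == ".csv" else _iter_jsonl(path)
    records, rejects = [], []
    for lineno, parsed, err in rows:
        if err is not None:
            rejects.append((lineno, err))
            continue
        try:
            rec = PatientRecord.from_dict(parsed)
            _validate_record(rec)
            records.append(rec)
        except (PainStringError, ValueError, TypeError, KeyError) as e:
            rejects.append((lineno, str(e)))
    if rejects_path is not None and rejects:
        with open(rejects_path, "w") as fh:
            for lineno, reason in rejects:
                fh.write(json.dumps({"row": lineno, "reason": reason}) + "\n")
    return records, rejects


def _iter_jsonl(path):
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                yield i, json.loads(line), None
            except json.JSONDecodeError as e:
                yield i, None, f"invalid JSON: {e}"


CSV_FIELDS = [
    "patient_id", "age", "weight", "height", "sex", "race", "preop_pain",
    "service", "urgency", "inpatient", "codes", "pain_obs",
    "died_intraop", "icu_admit",
]


def _write_csv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        w.writeheader()
        for rec in records:
            d = rec.to_dict()
            d["codes"] = "|".join(
                f"{k}:{c}" for c, k in sorted(rec.codes.items())
            )
            d["pain_obs"] = "|".join(f"{day}:{v}" for day, v in rec.pain_obs)
            d["preop_pain"] = "" if rec.preop_pain is None else rec.preop_pain
            w.writerow(d)


def _iter_csv(path):
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                yield i, _parse_csv_row(row), None
            except (ValueError, KeyError) as e:
                yield i, None, str(e)


def _parse_csv_row(row: dict) -> dict:
    codes = {}
    if row["codes"]:
        for item in row["codes"].split("|"):
            kind, code = item.split(":", 1)
            codes[code] = kind
    pain_obs = []
    if row["pain_obs"]:
        for item in row["pain_obs"].split("|"):
            day, value = item.split(":", 1)
            try:
                value = float(value)
            except ValueError:
                pass  # keep as string; validated against the vocabulary later
            pain_obs.append([int(day), value])
    return {
        "patient_id": row["patient_id"],
        "age": float(row["age"]),
        "weight": float(row["weight"]),
        "height": float(row["height"]),
        "sex": row["sex"],
        "race": row["race"],
        "preop_pain": None if row["preop_pain"] in ("", "None") else float(row["preop_pain"]),
        "service": row["service"],
        "urgency": row["urgency"],
        "inpatient": _BOOL[row["inpatient"].strip().lower()],
        "codes": codes,
        "pain_obs": pain_obs,
        "died_intraop": _BOOL[row["died_intraop"].strip().lower()],
        "icu_admit": _BOOL[row["icu_admit"].strip().lower()],
    }
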