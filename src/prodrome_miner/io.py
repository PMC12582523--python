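"""Validated readers/writers for cohort bundles.

On-disk layout (UTF-8 throughout):

* ``patients.csv``, ``labs.csv``, ``medications.csv`` — tabular records;
* ``notes.jsonl``, ``radiology.jsonl`` — one JSON object per line, because
  free text with embedded newlines is unsafe in CSV.

Writers are byte-stable: identical bundles serialize to identical bytes (no
timestamps, fixed column order, fixed key order).
"""

from __future__ import annotations

import csv
import json
import pathlib
from typing import Iterable

from pydantic import ValidationError

from prodrome_miner.data_model import (
    ClinicalNote,
    CohortBundle,
    LabResult,
    MedicationOrder,
    PatientRecord,
    RadiologyReport,
)


class BundleIOError(OSError):
    """A bundle file is missing or unwritable."""


class BundleValidationError(ValueError):
    """A row failed schema validation; message names file, row and field."""


_TABLES = {
    "patients": ("patients.csv", PatientRecord),
    "labs": ("labs.csv", LabResult),
    "medications": ("medications.csv", MedicationOrder),
    "notes": ("notes.jsonl", ClinicalNote),
    "radiology": ("radiology.jsonl", RadiologyReport),
}

_CSV_COLUMNS = {
    "patients": ["patient_id", "first_visit_date", "diagnosis_code", "stage",
                 "followup_end_date", "age_years", "sex", "height_cm", "weight_kg"],
    "labs": ["patient_id", "test_name", "result_date", "value", "units"],
    "medications": ["patient_id", "drug_name", "start_date", "end_date",
                    "drug_class", "indication"],
}


def bundle_paths(directory: str | pathlib.Path) -> dict[str, pathlib.Path]:
    d = pathlib.Path(directory)
    return {table: d / fname for table, (fname, _) in _TABLES.items()}


def _validate_row(model, payload: dict, table: str, row: int):
    try:
        return model.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"]) or "<record>"
        raise BundleValidationError(
            f"{table} row {row}: field {field!r}: {first['msg']}"
        ) from exc


def _read_csv_table(path: pathlib.Path, model, table: str) -> list:
    if not path.exists():
        raise BundleIOError(f"missing bundle file: {path}")
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=1):
            payload = {k: (None if v == "" else v) for k, v in row.items()}
            records.append(_validate_row(model, payload, table, i))
    return records


def _read_jsonl_table(path: pathlib.Path, model, table: str) -> list:
    if not path.exists():
        raise BundleIOError(f"missing bundle file: {path}")
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            records.append(_validate_row(model, json.loads(line), table, i))
    return records


def read_cohort_bundle(directory: str | pathlib.Path) -> CohortBundle:
    """Read and validate a full bundle; raises on any malformed row or
    orphan patient_id."""
    paths = bundle_paths(directory)
    bundle = CohortBundle(
        patients=_read_csv_table(paths["patients"], PatientRecord, "patients"),
        labs=_read_csv_table(paths["labs"], LabResult, "labs"),
        medications=_read_csv_table(paths["medications"], MedicationOrder, "medications"),
        notes=_read_jsonl_table(paths["notes"], ClinicalNote, "notes"),
        radiology=_read_jsonl_table(paths["radiology"], RadiologyReport, "radiology"),
    )
    bundle.check_referential_integrity()
    return bundle


def _csv_cell(value) -> str:
    if value is None:
        return ""
    if hasattr(value, "isoformat"):
        return value.isoformat()
    if hasattr(value, "value"):  # str enums
        return value.value
    return str(value)


def _write_csv_table(path: pathlib.Path, records: Iterable, table: str) -> None:
    columns = _CSV_COLUMNS[table]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            writer.writerow([_csv_cell(getattr(rec, c)) for c in columns])


def _write_jsonl_table(path: pathlib.Path, records: Iterable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(mode="json"), ensure_ascii=False,
                                sort_keys=True))
            fh.write("\n")


def write_cohort_bundle(bundle: CohortBundle, directory: str | pathlib.Path) -> None:
    """Validate the bundle and write all five files.

    Refuses to write a bundle with orphan patient_ids (per-record invariants
    are already enforced by the record types at construction time).
    """
    bundle.check_referential_integrity()
    d = pathlib.Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        paths = bundle_paths(d)
        _write_csv_table(paths["patients"], bundle.patients, "patients")
        _write_csv_table(paths["labs"], bundle.labs, "labs")
        _write_csv_table(paths["medications"], bundle.medications, "medications")
        _write_jsonl_table(paths["notes"], bundle.notes)
        _write_jsonl_table(paths["radiology"], bundle.radiology)
    except OSError as exc:
        raise BundleIOError(f"cannot write bundle under {d}: {exc}") from exc
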