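"""Lossless CSV interchange of mapping results.

The export writes one row per dictionary variable, in dictionary order,
with a fixed header.  Re-importing an export onto a fresh project over the
same dictionary and ontology reproduces the variable -> concept mapping set
exactly (the round-trip property); timestamps and user attribution belong
to the importing session, not the file.

Import never overwrites: a row that targets an already-mapped variable is
skipped and reported, matching the dashboard's delete-then-remap
discipline and making import idempotent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputOutputError, NotFoundError, PermissionDeniedError, SchemaError
from .session import MappingProject

#: Fixed export column set; extra columns in an import file are ignored.
EXPORT_COLUMNS = [
    "variable_id",
    "variable_name",
    "mapping_status",
    "concept_id",
    "concept_preferred_label",
    "mapped_by",
    "mapped_at",
    "n_comments",
]

EXPORT_HEADER = ",".join(EXPORT_COLUMNS)


def _iso_z(ts) -> str:
    from .session import _iso

    return _iso(ts)


def export_mappings_csv(project: MappingProject, path: str | Path) -> int:
    """Write the project's mapping results as CSV; returns the row count.

    One row per dictionary variable, dictionary order, LF line endings.
    Status is ``M`` with the concept columns filled when the variable is
    mapped, ``U`` with those columns empty otherwise.  ``n_comments`` is
    informational (the dashboard badge) and ignored on import.
    """
    path = Path(path)
    try:
        handle = path.open("w", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot write mappings CSV {path}: {exc}") from exc

    count = 0
    with handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(EXPORT_COLUMNS)
        for variable in project.dictionary.variables:
            record = project.mappings.get(variable.variable_id)
            if record is None:
                row = [variable.variable_id, variable.name, "U", "", "", "", ""]
            else:
                label = project.ontology.concepts[record.concept_id].preferred_label
                row = [
                    variable.variable_id,
                    variable.name,
                    "M",
                    record.concept_id,
                    label,
                    record.mapped_by,
                    _iso_z(record.mapped_at),
                ]
            row.append(str(project.comment_count(variable.variable_id)))
            writer.writerow(row)
            count += 1
    return count


@dataclass
class ImportReport:
    """Outcome of re-importing a mapping-results CSV."""

    applied: int = 0
    skipped: int = 0
    errors: list[str] = field(default_factory=list)


def import_mappings_csv(project: MappingProject, path: str | Path, user: str) -> ImportReport:
    """Apply the ``M`` rows of a mapping-results CSV to a project.

    For each ``M`` row: if the variable exists, the concept exists, and the
    variable is currently unmapped, the mapping is recorded (logged as MAP
    with detail ``"import"``).  Rows conflicting with an existing mapping
    are skipped, never overwritten.  ``U`` rows are no-ops.  Unknown
    variables or concepts are reported in ``errors`` without aborting the
    rest of the file.
    """
    if not project.has_can_map(user):
        raise PermissionDeniedError(f"user {user!r} lacks can_map on {project.name!r}")
    path = Path(path)
    try:
        handle = path.open("r", encoding="utf-8-sig", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot read mappings CSV {path}: {exc}") from exc

    report = ImportReport()
    with handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in EXPORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mapping-export column(s): {missing}")
        for line_no, row in enumerate(reader, start=2):
            status = (row.get("mapping_status") or "").strip()
            if status != "M":
                continue
            variable_id = (row.get("variable_id") or "").strip()
            concept_id = (row.get("concept_id") or "").strip()
            if not concept_id:
                report.errors.append(f"line {line_no}: status M but empty concept_id")
                continue
            if project.dictionary.get_variable(variable_id) is None:
                report.errors.append(f"line {line_no}: unknown variable {variable_id!r}")
                continue
            if concept_id not in project.ontology:
                report.errors.append(f"line {line_no}: unknown concept {concept_id!r}")
                continue
            if variable_id in project.mappings:
                report.skipped += 1
                continue
            project.record_mapping(user, variable_id, concept_id, detail="import")
            report.applied += 1
    return report
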