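"""Data-dictionary ingestion and variable browse/search.

A data dictionary is the catalogue of variables (data elements) collected by
a study or registry — here the mapping *source*.  It is loaded from a CSV
with a configurable field layout: which columns to import, which to show in
a browsing list, and which to show when a single variable is selected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ConfigError, InputOutputError, SchemaError


@dataclass
class FieldConfig:
    """Which dictionary columns are imported and where they are displayed.

    ``list_fields`` appear next to the variable name when browsing;
    ``detail_fields`` appear when one variable is selected.  Both must be
    subsets of ``import_fields``.
    """

    import_fields: list[str]
    list_fields: list[str] = field(default_factory=list)
    detail_fields: list[str] = field(default_factory=list)

    def validate(self) -> None:
        imported = set(self.import_fields)
        for role, fields in (("list", self.list_fields), ("detail", self.detail_fields)):
            extra = [f for f in fields if f not in imported]
            if extra:
                raise ConfigError(f"{role}_fields not in import_fields: {extra}")

    def to_dict(self) -> dict:
        return {
            "import_fields": list(self.import_fields),
            "list_fields": list(self.list_fields),
            "detail_fields": list(self.detail_fields),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FieldConfig":
        return cls(
            import_fields=list(d["import_fields"]),
            list_fields=list(d.get("list_fields", [])),
            detail_fields=list(d.get("detail_fields", [])),
        )


@dataclass
class Variable:
    """One data element to be mapped: identity, display name, raw fields."""

    variable_id: str
    name: str
    fields: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"variable_id": self.variable_id, "name": self.name, "fields": dict(self.fields)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Variable":
        return cls(d["variable_id"], d["name"], dict(d.get("fields", {})))


@dataclass
class DataDictionary:
    """An ordered collection of variables with its field configuration."""

    name: str
    variables: list[Variable]
    field_config: FieldConfig
    skipped_rows: int = 0

    def __len__(self) -> int:
        return len(self.variables)

    def get_variable(self, variable_id: str) -> Variable | None:
        for v in self.variables:
            if v.variable_id == variable_id:
                return v
        return None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "field_config": self.field_config.to_dict(),
            "variables": [v.to_dict() for v in self.variables],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DataDictionary":
        return cls(
            name=d["name"],
            variables=[Variable.from_dict(v) for v in d["variables"]],
            field_config=FieldConfig.from_dict(d["field_config"]),
        )


def load_dictionary_csv(
    path: str | Path,
    name_field: str,
    field_config: FieldConfig | None = None,
    id_field: str | None = None,
    name: str | None = None,
) -> DataDictionary:
    """Load a data dictionary from CSV (RFC 4180, UTF-8, header required).

    Variables keep source-file row order.  Rows whose ``name_field`` cell is
    empty are skipped with a warning count.  Variable identity for
    round-tripping is the ``id_field`` value when configured, otherwise the
    variable name; duplicate names get a ``#2``, ``#3`` ... suffix on the id.

    Raises
    ------
    SchemaError
        Missing ``name_field``/``id_field`` column, or duplicate explicit ids.
    ConfigError
        A list/detail field that is not imported.
    """
    path = Path(path)
    try:
        handle = path.open("r", encoding="utf-8-sig", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot read dictionary CSV {path}: {exc}") from exc

    with handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, header row required")
        if name_field not in header:
            raise SchemaError(f"{path}: name field {name_field!r} not in header")
        if id_field is not None and id_field not in header:
            raise SchemaError(f"{path}: id field {id_field!r} not in header")

        if field_config is None:
            field_config = FieldConfig(import_fields=list(header))
        missing = [f for f in field_config.import_fields if f not in header]
        if missing:
            raise SchemaError(f"{path}: import fields not in header: {missing}")
        field_config.validate()

        variables: list[Variable] = []
        seen_ids: dict[str, int] = {}
        skipped = 0
        for row in reader:
            varname = (row.get(name_field) or "").strip()
            if not varname:
                skipped += 1
                continue
            fields = {f: (row.get(f) or "") for f in field_config.import_fields}
            if id_field is not None:
                vid = (row.get(id_field) or "").strip()
                if not vid:
                    skipped += 1
                    continue
                if vid in seen_ids:
                    raise SchemaError(f"{path}: duplicate variable id {vid!r}")
                seen_ids[vid] = 1
            else:
                count = seen_ids.get(varname, 0) + 1
                seen_ids[varname] = count
                vid = varname if count == 1 else f"{varname}#{count}"
            variables.append(Variable(variable_id=vid, name=varname, fields=fields))

    return DataDictionary(
        name=name or path.stem,
        variables=variables,
        field_config=field_config,
        skipped_rows=skipped,
    )


def search_variables(dictionary: DataDictionary, keyword: str) -> list[Variable]:
    """Case-insensitive substring search over names and list fields.

    An empty keyword returns every variable (browsing mode).  Results always
    preserve dictionary order, so they form a subsequence of
    ``dictionary.variables``.
    """
    if not keyword:
        return list(dictionary.variables)
    needle = keyword.lower()
    hits = []
    for variable in dictionary.variables:
        haystacks = [variable.name] + [
            variable.fields.get(f, "") for f in dictionary.field_config.list_fields
        ]
        if any(needle in h.lower() for h in haystacks):
            hits.append(variable)
    return hits
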