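"""Ontology ingestion and hierarchy access.

Ontologies arrive as CSV exports in the BioPortal dialect: one row per
concept, a ``Class ID`` column with an opaque identifier (typically an IRI),
a ``Preferred Label``, and optional multi-valued ``Synonyms`` and ``Parents``
columns whose cells use ``|`` as the value separator.  The loader validates
the parent relation (it must be acyclic), drops references to concepts
outside the export, and derives the set of root concepts — those with no
retained parents — which anchor the hierarchy forest used for visualization.
"""

from __future__ import annotations

import csv
import unicodedata
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import CycleError, InputOutputError, NotFoundError, SchemaError

#: Default column names of a BioPortal CSV export, by role.
DEFAULT_COLUMNS = {
    "id": "Class ID",
    "label": "Preferred Label",
    "synonyms": "Synonyms",
    "definition": "Definitions",
    "parents": "Parents",
}

#: Parent values treated as "no parent" markers rather than references.
DEFAULT_ROOT_MARKERS = frozenset({"owl:Thing"})

MULTI_VALUE_SEPARATOR = "|"


@dataclass
class Concept:
    """One ontology class: identifier, labels and parent links.

    ``parent_ids`` holds only references that resolved to concepts in the
    same ontology; unresolvable references are dropped at load time and
    counted in :class:`LoadWarnings`.  ``extra_fields`` keeps any further
    imported columns verbatim, keyed by column name.
    """

    concept_id: str
    preferred_label: str
    synonyms: list[str] = field(default_factory=list)
    definition: str | None = None
    parent_ids: list[str] = field(default_factory=list)
    extra_fields: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "concept_id": self.concept_id,
            "preferred_label": self.preferred_label,
            "synonyms": list(self.synonyms),
            "definition": self.definition,
            "parent_ids": list(self.parent_ids),
            "extra_fields": dict(self.extra_fields),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Concept":
        return cls(
            concept_id=d["concept_id"],
            preferred_label=d["preferred_label"],
            synonyms=list(d.get("synonyms", [])),
            definition=d.get("definition"),
            parent_ids=list(d.get("parent_ids", [])),
            extra_fields=dict(d.get("extra_fields", {})),
        )


@dataclass
class LoadWarnings:
    """Counts of recoverable issues encountered while loading."""

    duplicate_ids: int = 0
    dangling_parents: int = 0
    skipped_rows: int = 0


@dataclass
class Ontology:
    """A loaded ontology: concept index plus derived hierarchy roots."""

    name: str
    concepts: dict[str, Concept]
    field_schema: list[str]
    root_ids: list[str]
    label_field: str = DEFAULT_COLUMNS["label"]
    warnings: LoadWarnings = field(default_factory=LoadWarnings)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "field_schema": list(self.field_schema),
            "label_field": self.label_field,
            "concepts": [c.to_dict() for c in self.concepts.values()],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Ontology":
        concepts = {c["concept_id"]: Concept.from_dict(c) for c in d["concepts"]}
        roots = sorted(cid for cid, c in concepts.items() if not c.parent_ids)
        return cls(
            name=d["name"],
            concepts=concepts,
            field_schema=list(d["field_schema"]),
            root_ids=roots,
            label_field=d.get("label_field", DEFAULT_COLUMNS["label"]),
        )


def _split_multi(cell: str) -> list[str]:
    if not cell:
        return []
    return [part.strip() for part in cell.split(MULTI_VALUE_SEPARATOR) if part.strip()]


def _check_acyclic(concepts: Mapping[str, Concept]) -> None:
    graph = nx.DiGraph()
    graph.add_nodes_from(concepts)
    for concept in concepts.values():
        for pid in concept.parent_ids:
            graph.add_edge(concept.concept_id, pid)
    try:
        cycle_edges = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        return
    raise CycleError([u for u, _ in cycle_edges])


def load_ontology_csv(
    path: str | Path,
    import_fields: Sequence[str] | None = None,
    root_markers: Iterable[str] | None = None,
    name: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Ontology:
    """Load an ontology from a BioPortal-dialect CSV file.

    Parameters
    ----------
    path:
        CSV file (RFC 4180, UTF-8, header row required).
    import_fields:
        Column names to import beyond the mandatory class-id and
        preferred-label columns.  ``None`` imports every column present.
    root_markers:
        Parent values to discard as "top of hierarchy" markers
        (default ``{"owl:Thing"}``).
    name:
        Ontology name; defaults to the file stem.
    column_map:
        Optional remap of the roles ``id``, ``label``, ``synonyms``,
        ``definition``, ``parents`` to actual column names, for exports
        that deviate from the BioPortal defaults.

    Raises
    ------
    InputOutputError
        If the file cannot be read.
    SchemaError
        If the mandatory columns are missing.
    CycleError
        If the parent relation contains a cycle.
    """
    path = Path(path)
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    markers = set(DEFAULT_ROOT_MARKERS if root_markers is None else root_markers)

    try:
        handle = path.open("r", encoding="utf-8-sig", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot read ontology CSV {path}: {exc}") from exc

    warnings = LoadWarnings()
    with handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames
        if header is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in (columns["id"], columns["label"]) if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {missing}")

        if import_fields is None:
            selected = list(header)
        else:
            unknown = [f for f in import_fields if f not in header]
            if unknown:
                raise SchemaError(f"{path}: import fields not in header: {unknown}")
            selected = list(dict.fromkeys(import_fields))
            for mandatory in (columns["id"], columns["label"]):
                if mandatory not in selected:
                    selected.insert(0, mandatory)

        known_roles = {columns[r] for r in ("id", "label", "synonyms", "definition", "parents")}
        concepts: dict[str, Concept] = {}
        for row in reader:
            cid = (row.get(columns["id"]) or "").strip()
            if not cid:
                warnings.skipped_rows += 1
                continue
            if cid in concepts:
                warnings.duplicate_ids += 1
            synonyms = (
                _split_multi(row.get(columns["synonyms"]) or "")
                if columns["synonyms"] in selected
                else []
            )
            definition = (
                (row.get(columns["definition"]) or "").strip() or None
                if columns["definition"] in selected
                else None
            )
            parents = (
                _split_multi(row.get(columns["parents"]) or "")
                if columns["parents"] in selected
                else []
            )
            parents = list(dict.fromkeys(p for p in parents if p not in markers))
            extra = {
                col: (row.get(col) or "")
                for col in selected
                if col not in known_roles
            }
            concepts[cid] = Concept(
                concept_id=cid,
                preferred_label=unicodedata.normalize(
                    "NFC", (row.get(columns["label"]) or "").strip()
                ),
                synonyms=synonyms,
                definition=definition,
                parent_ids=parents,
                extra_fields=extra,
            )

    # Parent references outside the loaded slice are dropped, not fatal;
    # the affected concept may become a root.
    for concept in concepts.values():
        retained = [p for p in concept.parent_ids if p in concepts]
        warnings.dangling_parents += len(concept.parent_ids) - len(retained)
        concept.parent_ids = retained

    _check_acyclic(concepts)

    roots = sorted(cid for cid, c in concepts.items() if not c.parent_ids)
    return Ontology(
        name=name or path.stem,
        concepts=concepts,
        field_schema=selected,
        root_ids=roots,
        label_field=columns["label"],
        warnings=warnings,
    )


def get_concept(ontology: Ontology, concept_id: str) -> Concept:
    """Return the concept with ``concept_id`` or raise :class:`NotFoundError`."""
    try:
        return ontology.concepts[concept_id]
    except KeyError:
        raise NotFoundError("concept", concept_id) from None


def ancestors(ontology: Ontology, concept_id: str) -> set[str]:
    """Transitive closure over parent links, excluding the concept itself."""
    get_concept(ontology, concept_id)
    seen: set[str] = set()
    queue = deque(ontology.concepts[concept_id].parent_ids)
    while queue:
        pid = queue.popleft()
        if pid in seen:
            continue
        seen.add(pid)
        queue.extend(ontology.concepts[pid].parent_ids)
    return seen


def roots(ontology: Ontology) -> list[str]:
    """Root concept ids (no retained parents), lexicographically ordered."""
    return list(ontology.root_ids)
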