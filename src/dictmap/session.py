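"""Mapping project state: bindings, privileges, mappings, comments, log.

A :class:`MappingProject` ties one data dictionary (the source) to one
ontology (the target) and records curation state: at most one mapped concept
per variable ("M"/"U" status), per-variable comment threads, an access
control list with two privileges — ``can_edit`` (administrator level, which
subsumes mapping) and ``can_map`` — and an append-only activity log of every
MAP, UNMAP and COMMENT event.  Public projects accept mappings from any
user; private projects (the default) require an explicit grant.

Replaying the log from an empty project reconstructs the mapping state, so
the log doubles as an audit trail and an event source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

from .dictionary import DataDictionary
from .errors import (
    ConfigError,
    InputOutputError,
    NotFoundError,
    PermissionDeniedError,
    StateError,
    ValidationError,
)
from .ontology import Ontology

PROJECT_FILE_VERSION = 1

Clock = Callable[[], datetime]


def _utc_now() -> datetime:
    return datetime.now(timezone.utc)


def _iso(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%fZ")


def _parse_iso(text: str) -> datetime:
    return datetime.fromisoformat(text.replace("Z", "+00:00"))


@dataclass
class MappingRecord:
    variable_id: str
    concept_id: str
    mapped_by: str
    mapped_at: datetime

    def to_dict(self) -> dict:
        return {
            "variable_id": self.variable_id,
            "concept_id": self.concept_id,
            "mapped_by": self.mapped_by,
            "mapped_at": _iso(self.mapped_at),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MappingRecord":
        return cls(d["variable_id"], d["concept_id"], d["mapped_by"], _parse_iso(d["mapped_at"]))


@dataclass
class LogEntry:
    at: datetime
    user: str
    action: Literal["MAP", "UNMAP", "COMMENT"]
    variable_id: str
    concept_id: str | None = None
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "at": _iso(self.at),
            "user": self.user,
            "action": self.action,
            "variable_id": self.variable_id,
            "concept_id": self.concept_id,
            "detail": self.detail,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogEntry":
        return cls(
            _parse_iso(d["at"]), d["user"], d["action"], d["variable_id"],
            d.get("concept_id"), d.get("detail", ""),
        )


@dataclass
class Comment:
    at: datetime
    user: str
    body: str

    def to_dict(self) -> dict:
        return {"at": _iso(self.at), "user": self.user, "body": self.body}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Comment":
        return cls(_parse_iso(d["at"]), d["user"], d["body"])


@dataclass
class Privileges:
    can_edit: bool = False
    can_map: bool = False


@dataclass
class StatusSummary:
    mapped_count: int
    unmapped_count: int
    per_variable_status: dict[str, str]


@dataclass
class MappingProject:
    """One curation session binding a dictionary to a target ontology."""

    name: str
    description: str
    ontology: Ontology
    dictionary: DataDictionary
    owner: str
    visibility: Literal["public", "private"] = "private"
    default_search_field: str | None = None
    display_fields: list[str] = field(default_factory=list)
    acl: dict[str, Privileges] = field(default_factory=dict)
    mappings: dict[str, MappingRecord] = field(default_factory=dict)
    comments: dict[str, list[Comment]] = field(default_factory=dict)
    log: list[LogEntry] = field(default_factory=list)
    clock: Clock = field(default=_utc_now, repr=False, compare=False)

    # ----- privileges ------------------------------------------------------

    def has_can_edit(self, user: str) -> bool:
        if user == self.owner:
            return True
        priv = self.acl.get(user)
        return bool(priv and priv.can_edit)

    def has_can_map(self, user: str) -> bool:
        # every user may contribute mappings to a public project
        if self.visibility == "public" or user == self.owner:
            return True
        priv = self.acl.get(user)
        return bool(priv and (priv.can_map or priv.can_edit))

    def grant_privilege(self, actor: str, target: str, privilege: str) -> None:
        """Grant ``can_edit`` or ``can_map`` to ``target``.

        Requires the actor to hold ``can_edit``; granting ``can_edit`` also
        grants ``can_map`` (the administrator level subsumes mapping).
        """
        if privilege not in ("can_edit", "can_map"):
            raise ConfigError(f"unknown privilege {privilege!r}")
        if not self.has_can_edit(actor):
            raise PermissionDeniedError(f"user {actor!r} lacks can_edit on {self.name!r}")
        priv = self.acl.setdefault(target, Privileges())
        if privilege == "can_edit":
            priv.can_edit = True
            priv.can_map = True
        else:
            priv.can_map = True

    # ----- mapping state machine ------------------------------------------

    def _require_variable(self, variable_id: str) -> None:
        if self.dictionary.get_variable(variable_id) is None:
            raise NotFoundError("variable", variable_id)

    def record_mapping(
        self, user: str, variable_id: str, concept_id: str, detail: str = ""
    ) -> MappingRecord:
        """Map a variable to a concept (status U -> M) and log the event.

        A variable holds at most one mapping; re-mapping requires deleting
        the existing match first.  Many variables may map to one concept.
        """
        if not self.has_can_map(user):
            raise PermissionDeniedError(f"user {user!r} lacks can_map on {self.name!r}")
        self._require_variable(variable_id)
        if concept_id not in self.ontology:
            raise NotFoundError("concept", concept_id)
        if variable_id in self.mappings:
            raise StateError(
                f"variable {variable_id!r} is already mapped to "
                f"{self.mappings[variable_id].concept_id!r}; delete the existing match first"
            )
        now = self.clock()
        record = MappingRecord(variable_id, concept_id, user, now)
        self.mappings[variable_id] = record
        self.log.append(LogEntry(now, user, "MAP", variable_id, concept_id, detail))
        return record

    def remove_mapping(self, user: str, variable_id: str) -> None:
        """Delete a variable's mapping (status M -> U) and log the event."""
        if not self.has_can_map(user):
            raise PermissionDeniedError(f"user {user!r} lacks can_map on {self.name!r}")
        self._require_variable(variable_id)
        record = self.mappings.pop(variable_id, None)
        if record is None:
            raise StateError(f"variable {variable_id!r} is not mapped")
        self.log.append(
            LogEntry(self.clock(), user, "UNMAP", variable_id, record.concept_id)
        )

    def add_comment(self, user: str, variable_id: str, body: str) -> Comment:
        """Attach a comment to a variable's thread and log the event."""
        if not self.has_can_map(user):
            raise PermissionDeniedError(f"user {user!r} lacks can_map on {self.name!r}")
        self._require_variable(variable_id)
        if not body or not body.strip():
            raise ValidationError("comment body must be non-empty")
        now = self.clock()
        comment = Comment(now, user, body)
        self.comments.setdefault(variable_id, []).append(comment)
        self.log.append(LogEntry(now, user, "COMMENT", variable_id, None, body))
        return comment

    def comment_count(self, variable_id: str) -> int:
        return len(self.comments.get(variable_id, []))

    def status_summary(self) -> StatusSummary:
        """Dashboard counts: M iff a mapping record exists, U otherwise."""
        per_variable = {
            v.variable_id: ("M" if v.variable_id in self.mappings else "U")
            for v in self.dictionary.variables
        }
        mapped = sum(1 for s in per_variable.values() if s == "M")
        return StatusSummary(
            mapped_count=mapped,
            unmapped_count=len(per_variable) - mapped,
            per_variable_status=per_variable,
        )

    # ----- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": PROJECT_FILE_VERSION,
            "name": self.name,
            "description": self.description,
            "ontology_ref": self.ontology.name,
            "dictionary_ref": self.dictionary.name,
            "owner": self.owner,
            "visibility": self.visibility,
            "default_search_field": self.default_search_field,
            "display_fields": list(self.display_fields),
            "acl": {
                u: {"can_edit": p.can_edit, "can_map": p.can_map}
                for u, p in self.acl.items()
            },
            "mappings": [m.to_dict() for m in self.mappings.values()],
            "comments": {
                vid: [c.to_dict() for c in thread] for vid, thread in self.comments.items()
            },
            "log": [entry.to_dict() for entry in self.log],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        try:
            path.write_text(
                json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n",
                encoding="utf-8",
            )
        except OSError as exc:
            raise InputOutputError(f"cannot write project file {path}: {exc}") from exc

    @classmethod
    def from_dict(
        cls, d: Mapping, ontology: Ontology, dictionary: DataDictionary
    ) -> "MappingProject":
        if d.get("version") != PROJECT_FILE_VERSION:
            raise ValidationError(f"unsupported project file version {d.get('version')!r}")
        project = cls(
            name=d["name"],
            description=d.get("description", ""),
            ontology=ontology,
            dictionary=dictionary,
            owner=d["owner"],
            visibility=d.get("visibility", "private"),
            default_search_field=d.get("default_search_field"),
            display_fields=list(d.get("display_fields", [])),
        )
        project.acl = {
            u: Privileges(can_edit=p["can_edit"], can_map=p["can_map"])
            for u, p in d.get("acl", {}).items()
        }
        project.mappings = {
            m["variable_id"]: MappingRecord.from_dict(m) for m in d.get("mappings", [])
        }
        project.comments = {
            vid: [Comment.from_dict(c) for c in thread]
            for vid, thread in d.get("comments", {}).items()
        }
        project.log = [LogEntry.from_dict(entry) for entry in d.get("log", [])]
        return project

    @classmethod
    def load(
        cls, path: str | Path, ontology: Ontology, dictionary: DataDictionary
    ) -> "MappingProject":
        path = Path(path)
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except OSError as exc:
            raise InputOutputError(f"cannot read project file {path}: {exc}") from exc
        return cls.from_dict(data, ontology, dictionary)


def create_project(
    name: str,
    description: str,
    ontology: Ontology,
    dictionary: DataDictionary,
    owner: str,
    visibility: Literal["public", "private"] = "private",
    default_search_field: str | None = None,
    display_fields: Sequence[str] | None = None,
    clock: Clock = _utc_now,
) -> MappingProject:
    """Create a fresh project with validated field configuration.

    The owner implicitly holds both privileges.  ``default_search_field``
    and every display field must be columns imported with the ontology.
    """
    if visibility not in ("public", "private"):
        raise ConfigError(f"visibility must be public or private, got {visibility!r}")
    if default_search_field is None:
        default_search_field = ontology.label_field
    elif (
        default_search_field != ontology.label_field
        and default_search_field not in ontology.field_schema
    ):
        raise ConfigError(f"search field {default_search_field!r} not in ontology schema")
    display_fields = list(display_fields or [])
    bad = [f for f in display_fields if f not in ontology.field_schema]
    if bad:
        raise ConfigError(f"display fields not in ontology schema: {bad}")
    project = MappingProject(
        name=name,
        description=description,
        ontology=ontology,
        dictionary=dictionary,
        owner=owner,
        visibility=visibility,
        default_search_field=default_search_field,
        display_fields=display_fields,
        clock=clock,
    )
    project.acl[owner] = Privileges(can_edit=True, can_map=True)
    return project


def replay_log(
    log: Sequence[LogEntry], ontology: Ontology, dictionary: DataDictionary
) -> dict[str, str]:
    """Rebuild the variable -> concept mapping set from MAP/UNMAP events.

    The audit log is an event source: applying its entries in order to an
    empty state must reproduce the live project's mappings exactly.
    """
    state: dict[str, str] = {}
    for entry in log:
        if entry.action == "MAP":
            state[entry.variable_id] = entry.concept_id
        elif entry.action == "UNMAP":
            state.pop(entry.variable_id, None)
    return state
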