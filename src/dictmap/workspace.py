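"""On-disk workspace backing the command-line interface.

A workspace is a directory holding named ontologies, dictionaries and
projects as JSON documents — the library/CLI counterpart of the web
system's database.  Projects reference their ontology and dictionary by
name; loading a project re-attaches the referenced objects.
"""

from __future__ import annotations

import json
from pathlib import Path

from .dictionary import DataDictionary
from .errors import InputOutputError, NotFoundError
from .ontology import Ontology
from .session import MappingProject


class Workspace:
    def __init__(self, root: str | Path):
        self.root = Path(root)

    def _dir(self, kind: str) -> Path:
        d = self.root / kind
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _write(self, kind: str, name: str, payload: dict) -> None:
        path = self._dir(kind) / f"{name}.json"
        try:
            path.write_text(
                json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
            )
        except OSError as exc:
            raise InputOutputError(f"cannot write {path}: {exc}") from exc

    def _read(self, kind: str, name: str, label: str) -> dict:
        path = self.root / kind / f"{name}.json"
        if not path.exists():
            raise NotFoundError(label, name)
        try:
            return json.loads(path.read_text(encoding="utf-8"))
        except OSError as exc:
            raise InputOutputError(f"cannot read {path}: {exc}") from exc

    # ----- ontologies -------------------------------------------------------

    def save_ontology(self, ontology: Ontology) -> None:
        self._write("ontologies", ontology.name, ontology.to_dict())

    def load_ontology(self, name: str) -> Ontology:
        return Ontology.from_dict(self._read("ontologies", name, "ontology"))

    # ----- dictionaries -----------------------------------------------------

    def save_dictionary(self, dictionary: DataDictionary) -> None:
        self._write("dictionaries", dictionary.name, dictionary.to_dict())

    def load_dictionary(self, name: str) -> DataDictionary:
        return DataDictionary.from_dict(self._read("dictionaries", name, "dictionary"))

    # ----- projects ---------------------------------------------------------

    def save_project(self, project: MappingProject) -> None:
        self._write("projects", project.name, project.to_dict())

    def load_project(self, name: str) -> MappingProject:
        data = self._read("projects", name, "project")
        ontology = self.load_ontology(data["ontology_ref"])
        dictionary = self.load_dictionary(data["dictionary_ref"])
        return MappingProject.from_dict(data, ontology, dictionary)
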