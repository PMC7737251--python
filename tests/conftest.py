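import csv
import random
from datetime import datetime, timezone
from pathlib import Path

import pytest

from dictmap.dictionary import DataDictionary, FieldConfig, Variable
from dictmap.ontology import Concept, Ontology, load_ontology_csv

ONTOLOGY_HEADER = ["Class ID", "Preferred Label", "Synonyms", "Definitions", "Parents"]


def write_ontology_csv(path: Path, rows: list[list[str]]) -> Path:
    """Write a BioPortal-dialect ontology CSV from [id, label, syn, def, parents] rows."""
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ONTOLOGY_HEADER)
        writer.writerows(rows)
    return path


@pytest.fixture
def toy_ontology_csv(tmp_path: Path) -> Path:
    """A: root; B: child of A; C: child of A and B; D: parent is the root
    marker owl:Thing; E: parent X is dangling (dropped, E becomes a root)."""
    return write_ontology_csv(
        tmp_path / "toy.csv",
        [
            ["A", "Race", "Racial Group", "", ""],
            ["B", "Sex", "", "", "A"],
            ["C", "Birth Date", "Date of Birth|DOB", "", "A|B"],
            ["D", "Vital Status", "", "", "owl:Thing"],
            ["E", "Occupation", "", "", "X"],
        ],
    )


@pytest.fixture
def toy_ontology(toy_ontology_csv: Path) -> Ontology:
    return load_ontology_csv(toy_ontology_csv)


@pytest.fixture
def diamond_ontology(tmp_path: Path) -> Ontology:
    """R -> A, R -> B, A -> L, B -> L (L has two parents)."""
    path = write_ontology_csv(
        tmp_path / "diamond.csv",
        [
            ["R", "Root", "", "", ""],
            ["A", "Alpha", "", "", "R"],
            ["B", "Beta", "", "", "R"],
            ["L", "Leaf", "", "", "A|B"],
        ],
    )
    return load_ontology_csv(path)


def make_dictionary(names: list[str], name: str = "dict") -> DataDictionary:
    variables = [
        Variable(variable_id=n, name=n, fields={"Variable": n}) for n in names
    ]
    return DataDictionary(
        name=name, variables=variables, field_config=FieldConfig(import_fields=["Variable"])
    )


@pytest.fixture
def three_variable_dictionary() -> DataDictionary:
    return make_dictionary(["Race 1", "Sex", "Date Of Birth"])


def fixed_clock(start: float = 0.0):
    """Deterministic monotonically increasing clock for reproducible logs."""
    state = {"t": start}

    def clock() -> datetime:
        state["t"] += 1.0
        return datetime.fromtimestamp(1_600_000_000 + state["t"], tz=timezone.utc)

    return clock


def random_dag_ontology(rng: random.Random, n: int, extra_edge_rate: float = 0.3) -> Ontology:
    """Random DAG built in memory: edges only from later to earlier indices."""
    concepts = {}
    for i in range(n):
        parents = []
        if i > 0 and rng.random() < 0.9:
            parents.append(f"N{rng.randrange(i):03d}")
        if i > 1 and rng.random() < extra_edge_rate:
            second = f"N{rng.randrange(i):03d}"
            if second not in parents:
                parents.append(second)
        concepts[f"N{i:03d}"] = Concept(
            concept_id=f"N{i:03d}",
            preferred_label=f"label {i}",
            parent_ids=parents,
        )
    roots = sorted(cid for cid, c in concepts.items() if not c.parent_ids)
    return Ontology(
        name="random-dag",
        concepts=concepts,
        field_schema=list(ONTOLOGY_HEADER),
        root_ids=roots,
    )
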