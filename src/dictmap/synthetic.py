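"""Synthetic ontologies and dictionaries with planted ground truth.

Desk-scale stand-ins for a real terminology and registry data dictionary:
a random rooted concept hierarchy (a tree, plus a small rate of extra
cross-parents so the multi-parent DAG paths are exercised) with distinct
multi-word labels drawn from a bundled vocabulary, and a dictionary whose
variable names are concept labels perturbed by random character edits —
optionally with an appended numeric suffix token, emulating "Race 1"-style
registry variables.  The planted (variable, concept) pairs are emitted as a
gold mapping list, so recommendation accuracy can be evaluated end to end
without any external download.

Everything is driven by one explicitly seeded pseudo-random generator; the
same spec and seed reproduce byte-identical CSV files.

The package also bundles a small expert-verified fixture: 47 cancer-registry
variables with their verified target concepts (many-to-one: five "Race N"
variables share one concept), as a gold list, a mapping-results CSV in the
interchange format, a 43-concept fixture ontology, and the 47-variable
dictionary.
"""

from __future__ import annotations

import csv
import random
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .dictionary import DataDictionary, FieldConfig, Variable, load_dictionary_csv
from .errors import ConfigError, InputOutputError
from .ontology import Ontology, load_ontology_csv

#: Fraction of non-root concepts that receive a second parent.
DEFAULT_CROSS_PARENT_RATE = 0.05

#: Probability of appending a numeric suffix token to a perturbed name.
DEFAULT_SUFFIX_PROBABILITY = 0.3


@dataclass
class SyntheticSpec:
    """Shape and noise parameters of one synthetic dataset."""

    n_concepts: int
    max_children: int = 4
    depth: int = 5
    n_variables: int = 0
    perturb_rate: float = 0.0
    seed: int = 0
    cross_parent_rate: float = DEFAULT_CROSS_PARENT_RATE

    def validate(self) -> None:
        if self.n_concepts < 1:
            raise ConfigError("n_concepts must be >= 1")
        if self.max_children < 1 or self.depth < 1:
            raise ConfigError("max_children and depth must be >= 1")
        if not 0.0 <= self.perturb_rate <= 1.0:
            raise ConfigError("perturb_rate must be in [0, 1]")
        if self.n_variables < 0 or self.n_variables > self.n_concepts:
            raise ConfigError("n_variables must be in [0, n_concepts]")
        # capacity of a tree with this fan-out and depth (root = level 1)
        capacity, width = 0, 1
        for _ in range(self.depth):
            capacity += width
            width *= self.max_children
            if capacity >= self.n_concepts:
                return
        if capacity < self.n_concepts:
            raise ConfigError(
                f"depth {self.depth} with max_children {self.max_children} "
                f"can host at most {capacity} concepts, got {self.n_concepts}"
            )


def _vocabulary() -> list[str]:
    text = resources.files("dictmap").joinpath("data/vocabulary.txt").read_text("utf-8")
    return [w for w in text.split() if w]


def _distinct_labels(n: int, rng: random.Random) -> list[str]:
    """Labels whose token sets are pairwise subset-free.

    Subset-free token sets guarantee that an unperturbed variable name has a
    unique top-scoring concept: the token-set ratio reaches 100 only when one
    token set contains the other.
    """
    words = _vocabulary()
    labels: list[str] = []
    token_sets: list[frozenset[str]] = []
    attempts = 0
    while len(labels) < n:
        k = rng.choice((2, 2, 3))  # mostly two-word labels
        chosen = [rng.choice(words) for _ in range(k)]
        tokens = frozenset(w.lower() for w in chosen)
        attempts += 1
        if attempts > 200 * n:
            raise ConfigError(
                f"vocabulary too small to draw {n} subset-free labels"
            )
        if any(tokens <= other or other <= tokens for other in token_sets):
            continue
        token_sets.append(tokens)
        labels.append(" ".join(w.capitalize() for w in chosen))
    return labels


def generate_synthetic_ontology(spec: SyntheticSpec, out_path: str | Path) -> Ontology:
    """Write a random concept hierarchy as a BioPortal-dialect CSV and load it.

    The hierarchy is a rooted tree respecting ``max_children`` and ``depth``
    (root at level 1); a ``cross_parent_rate`` fraction of non-root concepts
    get a second parent at a strictly smaller depth, which keeps the parent
    relation acyclic.  Returning the loader's output guarantees the file is
    in exactly the dialect :func:`dictmap.ontology.load_ontology_csv` reads.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    n = spec.n_concepts
    labels = _distinct_labels(n, rng)
    ids = [f"SYN:{i:04d}" for i in range(n)]

    depth_of = [1] + [0] * (n - 1)
    n_children = [0] * n
    parents: list[list[int]] = [[] for _ in range(n)]
    eligible = [0]  # indices that may still accept children
    for i in range(1, n):
        parent = rng.choice(eligible)
        parents[i].append(parent)
        depth_of[i] = depth_of[parent] + 1
        n_children[parent] += 1
        if n_children[parent] >= spec.max_children:
            eligible.remove(parent)
        if depth_of[i] < spec.depth:
            eligible.append(i)

    for i in range(1, n):
        if depth_of[i] >= 3 and rng.random() < spec.cross_parent_rate:
            shallower = [j for j in range(n) if depth_of[j] < depth_of[i] and j not in parents[i]]
            if shallower:
                parents[i].append(rng.choice(shallower))

    out_path = Path(out_path)
    try:
        handle = out_path.open("w", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot write ontology CSV {out_path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["Class ID", "Preferred Label", "Synonyms", "Definitions", "Parents"])
        for i in range(n):
            writer.writerow(
                [ids[i], labels[i], "", "", "|".join(ids[p] for p in parents[i])]
            )
    return load_ontology_csv(out_path, name=out_path.stem)


def _perturb(label: str, rate: float, rng: random.Random) -> str:
    """Apply random character edits at an expected per-character rate."""
    out: list[str] = []
    for ch in label:
        if rng.random() < rate:
            op = rng.choice(("substitute", "insert", "delete"))
            if op == "substitute":
                out.append(rng.choice(string.ascii_lowercase))
            elif op == "insert":
                out.append(ch)
                out.append(rng.choice(string.ascii_lowercase))
            # delete: drop the character
        else:
            out.append(ch)
    text = "".join(out).strip()
    return text if text else rng.choice(string.ascii_lowercase)


def generate_perturbed_dictionary(
    ontology: Ontology,
    n_variables: int,
    perturb_rate: float,
    seed: int,
    suffix_probability: float = DEFAULT_SUFFIX_PROBABILITY,
    name: str = "synthetic-dictionary",
) -> tuple[DataDictionary, list[tuple[Variable, str]]]:
    """Sample concepts and emit variables whose names are noisy labels.

    Each of ``n_variables`` concepts (sampled without replacement) yields
    one variable: its name is the concept label with random character edits
    at the stated expected rate, plus — with probability
    ``suffix_probability`` — an appended numeric suffix token.  Returns the
    dictionary and the planted gold (variable, concept id) list.
    """
    if n_variables > len(ontology.concepts):
        raise ConfigError(
            f"n_variables {n_variables} exceeds concept count {len(ontology.concepts)}"
        )
    rng = random.Random(seed)
    concept_ids = sorted(ontology.concepts)
    chosen = rng.sample(concept_ids, n_variables)

    variables: list[Variable] = []
    gold: list[tuple[Variable, str]] = []
    seen: dict[str, int] = {}
    for cid in chosen:
        label = ontology.concepts[cid].preferred_label
        varname = _perturb(label, perturb_rate, rng)
        if rng.random() < suffix_probability:
            varname = f"{varname} {rng.randint(1, 9)}"
        count = seen.get(varname, 0) + 1
        seen[varname] = count
        vid = varname if count == 1 else f"{varname}#{count}"
        variable = Variable(variable_id=vid, name=varname, fields={"Variable": varname})
        variables.append(variable)
        gold.append((variable, cid))

    dictionary = DataDictionary(
        name=name,
        variables=variables,
        field_config=FieldConfig(import_fields=["Variable"]),
    )
    return dictionary, gold


def write_dictionary_csv(dictionary: DataDictionary, path: str | Path) -> None:
    """Write a dictionary in the CSV dialect :func:`load_dictionary_csv` reads."""
    try:
        handle = Path(path).open("w", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot write dictionary CSV {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["Variable"])
        for variable in dictionary.variables:
            writer.writerow([variable.name])


def write_gold_csv(gold: Sequence[tuple[Variable, str]], path: str | Path) -> None:
    """Write a gold mapping list as ``variable_id,variable_name,concept_id``."""
    try:
        handle = Path(path).open("w", encoding="utf-8", newline="")
    except OSError as exc:
        raise InputOutputError(f"cannot write gold CSV {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["variable_id", "variable_name", "concept_id"])
        for variable, concept_id in gold:
            writer.writerow([variable.variable_id, variable.name, concept_id])


def load_gold_csv(path: str | Path) -> list[tuple[str, str]]:
    """Read a gold list back as (variable name, concept id) pairs."""
    with Path(path).open("r", encoding="utf-8-sig", newline="") as handle:
        reader = csv.DictReader(handle)
        return [(row["variable_name"], row["concept_id"]) for row in reader]


# ----- packaged expert-verified fixture -------------------------------------


@dataclass
class Table1Fixture:
    """The bundled expert-verified registry-to-terminology mapping sample."""

    ontology: Ontology
    dictionary: DataDictionary
    gold: list[tuple[str, str]]  # (variable name == variable id, concept id)
    mappings_csv: Path


def fixture_path(filename: str) -> Path:
    """Absolute path of a bundled data file."""
    return Path(str(resources.files("dictmap").joinpath(f"data/{filename}")))


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 47-pair expert-verified mapping fixture.

    47 registry variables map many-to-one onto 43 distinct target concepts;
    the fixture ships as a flat 43-concept ontology, a 47-variable
    dictionary, a gold list, and a ready-to-import mapping-results CSV.
    """
    ontology = load_ontology_csv(fixture_path("table1_ontology.csv"), name="table1-ontology")
    dictionary = load_dictionary_csv(
        fixture_path("table1_dictionary.csv"),
        name_field="Variable",
        name="table1-dictionary",
    )
    gold = load_gold_csv(fixture_path("table1_gold.csv"))
    return Table1Fixture(
        ontology=ontology,
        dictionary=dictionary,
        gold=gold,
        mappings_csv=fixture_path("table1_mappings.csv"),
    )
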