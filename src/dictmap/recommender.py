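"""Fuzzy concept recommendation.

For each dictionary variable the engine scores every concept of the target
ontology by string similarity between the variable name and the concept's
match field (the preferred label by default, optionally its synonyms too)
and returns the top ``k`` candidates, ranked by score.

The scorer is the maximum of two normalized Levenshtein ratios on a 0–100
scale:

* the *full ratio* ``100 * (1 - lev(x, y) / max(|x|, |y|))``, which captures
  character-level edit noise ("Ruralurban" vs "Rural-Urban"); and
* the *token-set ratio*, which compares the sorted unique token sets of the
  two strings through their intersection and differences, so that
  word-order changes and token subsets ("Race 1" vs "Race") score 100.

Both inputs are normalized first (Unicode NFKC, lower case, punctuation to
spaces, whitespace collapsed).  Edit distances are computed with edlib.

A priority queue keeps only the running top ``k`` while scanning the
ontology; the result is by contract identical to scoring every concept and
sorting by (score desc, normalized candidate text asc, concept id asc).
"""

from __future__ import annotations

import heapq
import unicodedata
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import edlib

from .dictionary import Variable
from .errors import ConfigError, ValidationError
from .ontology import Concept, Ontology

def normalize_text(s: str) -> str:
    """NFKC-normalize, lower-case, strip punctuation, collapse whitespace."""
    s = unicodedata.normalize("NFKC", s).lower()
    cleaned = "".join(ch if ch.isalnum() else " " for ch in s)
    return " ".join(cleaned.split())


def _dp_levenshtein(x: str, y: str) -> int:
    prev = list(range(len(y) + 1))
    for i, cx in enumerate(x, start=1):
        cur = [i]
        for j, cy in enumerate(y, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cx != cy)))
        prev = cur
    return prev[-1]


def _levenshtein(x: str, y: str) -> int:
    if not x:
        return len(y)
    if not y:
        return len(x)
    try:
        return edlib.align(x, y, task="distance")["editDistance"]
    except Exception:  # edlib caps the alphabet at 256 distinct symbols
        return _dp_levenshtein(x, y)


def full_ratio(x: str, y: str) -> float:
    """Normalized Levenshtein similarity of two raw strings, in [0, 100]."""
    longest = max(len(x), len(y))
    if longest == 0:
        return 100.0
    return 100.0 * (1.0 - _levenshtein(x, y) / longest)


def token_set_ratio(x: str, y: str) -> float:
    """Similarity of sorted unique token sets, robust to order and subsets."""
    t_x = sorted(set(x.split()))
    t_y = sorted(set(y.split()))
    common = sorted(set(t_x) & set(t_y))
    only_x = sorted(set(t_x) - set(t_y))
    only_y = sorted(set(t_y) - set(t_x))
    i = " ".join(common)
    u_x = " ".join(common + only_x)
    u_y = " ".join(common + only_y)
    return max(full_ratio(i, u_x), full_ratio(i, u_y), full_ratio(u_x, u_y))


def similarity_score(a: str, b: str) -> float:
    """Similarity of two texts in [0, 100]; symmetric; 0 if either is blank."""
    na, nb = normalize_text(a), normalize_text(b)
    if not na or not nb:
        return 0.0
    return max(full_ratio(na, nb), token_set_ratio(na, nb))


@dataclass
class Recommendation:
    """One ranked candidate concept for a variable."""

    concept_id: str
    label: str
    score: float
    rank: int


def _field_value(concept: Concept, field_name: str, ontology: Ontology) -> str:
    if field_name == ontology.label_field:
        return concept.preferred_label
    if field_name in concept.extra_fields:
        return concept.extra_fields[field_name]
    if concept.definition is not None and field_name.lower().startswith("definition"):
        return concept.definition
    return ""


def recommend_top_k(
    variable: Variable | str,
    ontology: Ontology,
    k: int = 10,
    search_field: str | None = None,
    include_synonyms: bool = False,
) -> list[Recommendation]:
    """Rank the ``k`` most similar ontology concepts for a variable.

    ``search_field`` selects which imported ontology column supplies the
    candidate text (default: the preferred label).  With
    ``include_synonyms`` each concept scores as the maximum over its match
    field and all its synonyms.  Ties are broken by normalized candidate
    text, then concept id, so the ranking is deterministic.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if search_field is None:
        search_field = ontology.label_field
    elif search_field != ontology.label_field and search_field not in ontology.field_schema:
        raise ConfigError(f"search field {search_field!r} not in ontology schema")

    query = variable.name if isinstance(variable, Variable) else variable

    # Priority queue of the best k seen so far; final order is identical to
    # a full sort by (score desc, normalized text asc, id asc).
    entries = []
    for concept in ontology.concepts.values():
        text = _field_value(concept, search_field, ontology)
        score = similarity_score(query, text)
        if include_synonyms:
            for synonym in concept.synonyms:
                score = max(score, similarity_score(query, synonym))
        entries.append((-score, normalize_text(text), concept.concept_id, concept))

    top = heapq.nsmallest(k, entries)
    return [
        Recommendation(
            concept_id=concept.concept_id,
            label=concept.preferred_label,
            score=-neg_score,
            rank=rank,
        )
        for rank, (neg_score, _text, _cid, concept) in enumerate(top, start=1)
    ]


@dataclass
class AccuracyReport:
    """Top-k evaluation of the engine against a verified gold mapping set."""

    k: int
    n_pairs: int
    n_hits: int
    accuracy: float
    #: hit rank within the top-k list per variable name, None for a miss
    hit_ranks: dict[str, int | None] = dc_field(default_factory=dict)


def top_k_accuracy(
    gold: Sequence[tuple[Variable | str, str]],
    ontology: Ontology,
    k: int,
    search_field: str | None = None,
    include_synonyms: bool = False,
) -> AccuracyReport:
    """Fraction of gold (variable, concept) pairs recovered in the top ``k``.

    Every gold concept id must exist in the ontology.  Also reports, per
    variable, the rank at which its verified concept appeared (or ``None``).
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    for variable, concept_id in gold:
        if concept_id not in ontology:
            name = variable.name if isinstance(variable, Variable) else variable
            raise ValidationError(
                f"gold concept {concept_id!r} (for variable {name!r}) not in ontology"
            )

    hit_ranks: dict[str, int | None] = {}
    hits = 0
    for variable, concept_id in gold:
        name = variable.name if isinstance(variable, Variable) else variable
        recs = recommend_top_k(
            variable, ontology, k=k, search_field=search_field,
            include_synonyms=include_synonyms,
        )
        rank = next((r.rank for r in recs if r.concept_id == concept_id), None)
        hit_ranks[name] = rank
        if rank is not None:
            hits += 1
    n = len(gold)
    return AccuracyReport(
        k=k,
        n_pairs=n,
        n_hits=hits,
        accuracy=hits / n if n else 0.0,
        hit_ranks=hit_ranks,
    )
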