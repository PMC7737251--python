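"""Hierarchy branches induced by mapped concepts.

After curation, each mapped concept is treated as a leaf and traced up
through every parent link to the hierarchy roots of the target ontology.
The union of these root-to-leaf paths, grouped by the root they reach,
forms a forest of *branches*: one branch per root that at least one mapped
concept can reach.  A branch records its unique members, the parent edges
among them, the mapped subset, and two summary statistics — node count and
maximum level (root = level 1, levels counted in nodes along the longest
root-to-member path).

Branch membership is deliberately paths-only: ancestors of mapped concepts
plus the mapped concepts themselves.  Siblings and other descendants of
path nodes are not pulled in, which keeps branches proportional to the
mapping set rather than to the ontology.

For rendering, a branch (a DAG in general, since concepts may have several
parents) is expanded into a nested tree: a member with multiple in-branch
parents is duplicated under each parent.  Statistics are always computed on
the unique-member DAG, not on the expanded tree.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputOutputError, NotFoundError
from .ontology import Ontology, ancestors, get_concept


@dataclass
class Branch:
    """The sub-hierarchy reaching one root from a set of mapped concepts."""

    root_id: str
    member_ids: set[str]
    mapped_ids: set[str]
    edges: set[tuple[str, str]]  # (parent_id, child_id), both members
    node_count: int = 0
    max_level: int = 0

    def __post_init__(self) -> None:
        if not self.node_count:
            self.node_count = len(self.member_ids)
        if not self.max_level:
            self.max_level = _max_level(self.root_id, self.edges, self.member_ids)


def _max_level(root_id: str, edges: set[tuple[str, str]], members: set[str]) -> int:
    """Longest root-to-member path, counted in nodes (root alone = 1).

    The branch restricted to its edges is a DAG with every member reachable
    from the root, so a topological sweep yields longest distances.
    """
    children: dict[str, list[str]] = {m: [] for m in members}
    indegree: dict[str, int] = {m: 0 for m in members}
    for parent, child in edges:
        children[parent].append(child)
        indegree[child] += 1
    level = {m: 1 for m in members}
    queue = [m for m in members if indegree[m] == 0]
    order: list[str] = []
    while queue:
        node = queue.pop()
        order.append(node)
        for child in children[node]:
            level[child] = max(level[child], level[node] + 1)
            indegree[child] -= 1
            if indegree[child] == 0:
                queue.append(child)
    return max(level.values()) if members else 0


def extract_branches(ontology: Ontology, mapped_concept_ids: Iterable[str]) -> list[Branch]:
    """Build the branch forest induced by a set of mapped concepts.

    Every mapped concept contributes its ancestor closure (over *all* parent
    links); members are grouped by the root(s) they reach, one branch per
    root reached by at least one mapped concept, ordered by root id.  A
    concept that reaches two roots appears in both branches.  Edges are the
    ontology parent links restricted to branch members.
    """
    mapped = set(mapped_concept_ids)
    for cid in mapped:
        if cid not in ontology:
            raise NotFoundError("concept", cid)
    if not mapped:
        return []

    # closure of the mapped set: every node on some root-to-mapped path
    all_members: set[str] = set()
    for cid in mapped:
        all_members.add(cid)
        all_members |= ancestors(ontology, cid)

    # roots reachable from each member (memoized over the member closure)
    root_set = set(ontology.root_ids)
    roots_of: dict[str, set[str]] = {}
    for member in all_members:
        up = ancestors(ontology, member) | {member}
        roots_of[member] = up & root_set

    branch_roots = sorted(set().union(*(roots_of[cid] for cid in mapped)))

    branches: list[Branch] = []
    for root in branch_roots:
        members = {m for m in all_members if root in roots_of[m]}
        edges = {
            (parent, child)
            for child in members
            for parent in ontology.concepts[child].parent_ids
            if parent in members
        }
        branches.append(
            Branch(
                root_id=root,
                member_ids=members,
                mapped_ids=mapped & members,
                edges=edges,
            )
        )
    return branches


def branch_statistics(branches: Sequence[Branch], ontology: Ontology):
    """Summary table of the branch forest: one row per branch, input order.

    Returns a pandas DataFrame with columns ``root_id``, ``root_label``,
    ``node_count``, ``max_level``.
    """
    import pandas as pd

    rows = [
        {
            "root_id": b.root_id,
            "root_label": get_concept(ontology, b.root_id).preferred_label,
            "node_count": b.node_count,
            "max_level": b.max_level,
        }
        for b in branches
    ]
    return pd.DataFrame(rows, columns=["root_id", "root_label", "node_count", "max_level"])


def write_branch_statistics_csv(
    branches: Sequence[Branch], ontology: Ontology, path: str | Path
) -> None:
    """Write the statistics table as CSV with LF line endings."""
    table = branch_statistics(branches, ontology)
    try:
        with Path(path).open("w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(table.columns.tolist())
            writer.writerows(table.itertuples(index=False))
    except OSError as exc:
        raise InputOutputError(f"cannot write statistics CSV {path}: {exc}") from exc


def to_nested_tree(branch: Branch, ontology: Ontology) -> dict:
    """Expand a branch into the nested node structure tree renderers consume.

    Each node is ``{"id", "label", "role", "children"}`` with role
    ``"mapped"`` for mapped concepts (including a mapped root) and
    ``"intermediate"`` otherwise.  Children are ordered by (label, id).  A
    member with several in-branch parents is duplicated under each parent,
    so the tree may repeat ids that the branch counts once.
    """
    children_of: dict[str, list[str]] = {m: [] for m in branch.member_ids}
    for parent, child in branch.edges:
        children_of[parent].append(child)

    def build(concept_id: str) -> dict:
        concept = get_concept(ontology, concept_id)
        kids = sorted(
            children_of[concept_id],
            key=lambda cid: (get_concept(ontology, cid).preferred_label, cid),
        )
        return {
            "id": concept_id,
            "label": concept.preferred_label,
            "role": "mapped" if concept_id in branch.mapped_ids else "intermediate",
            "children": [build(cid) for cid in kids],
        }

    return build(branch.root_id)


def write_nested_tree_json(branch: Branch, ontology: Ontology, path: str | Path) -> None:
    """Serialize one branch's nested tree as UTF-8 JSON."""
    tree = to_nested_tree(branch, ontology)
    try:
        Path(path).write_text(
            json.dumps(tree, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
    except OSError as exc:
        raise InputOutputError(f"cannot write tree JSON {path}: {exc}") from exc
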