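# Methods

## Problem and model

`dictmap` supports curated mapping from a data dictionary (a catalogue of
variables collected by a study or registry) to a target ontology (a
structured vocabulary of concepts with preferred labels, synonyms and is-a
parent links). The mapping is an expert decision; the software contributes
(i) a deterministic similarity ranking that proposes candidate concepts,
(ii) a session model that makes the curation auditable and collaborative,
and (iii) hierarchy summaries that show where the mapped concepts sit in the
target terminology.

The core assumptions are:

- the parent relation of the ontology is a DAG (cycles are a load-time
  error); a concept may have several parents, and the hierarchy is a forest
  whose roots are the concepts with no retained parents;
- one variable maps to at most one concept at a time, while many variables
  may map to the same concept (many-to-one);
- string similarity between a variable's name and a concept's label is a
  useful — not authoritative — signal for ranking candidates.

## Similarity scorer

Both inputs are normalized: Unicode NFKC, lower case, every non-alphanumeric
character replaced by a space, whitespace collapsed. If either normalized
string is empty the score is 0 (a blank never "matches" anything, including
another blank). Otherwise the score is the maximum of:

- **full ratio** `100 * (1 − lev(x, y) / max(|x|, |y|))`, Levenshtein
  distance on the whole normalized strings — sensitive to character-level
  noise such as missing hyphens or typos;
- **token-set ratio** — the sorted unique token sets are compared through
  their intersection and differences (intersection string vs each combined
  string, and the two combined strings against each other, taking the best
  full ratio). This reaches 100 exactly when one token set contains the
  other, which is what makes "Race 1" score 100 against "Race" and makes the
  scorer order-insensitive ("Date Of Birth" vs "Birth Date").

The two components cover the two error modes that dominate real
dictionary-to-terminology comparisons: edit noise and token subset/reorder.
The scorer is symmetric and bounded in [0, 100]; identical non-blank
normalized inputs always score 100. Edit distances are computed by `edlib`
(C); a pure-Python dynamic program stands in for inputs outside edlib's
256-symbol alphabet limit. The test suite cross-checks the full ratio
against an independent dynamic-programming oracle.

## Ranking

`recommend_top_k` scores every concept's match field (preferred label by
default; any imported column may be selected, and synonym matching is
opt-in, taking the maximum over label and synonyms). Candidates are ordered
by **(score desc, normalized candidate text asc, concept id asc)** and the
first *k* are returned. The engine tracks k = 10 by default while the CLI
displays the top 5; a bounded priority queue (`heapq.nsmallest`) avoids a
full sort, but the contract — tested property — is extensional equality
with score-everything-then-sort. The deterministic tie-break matters in
practice: near-duplicate labels frequently tie at the same score, and
without it evaluation numbers would not be reproducible.

Evaluation (`top_k_accuracy`) reports the fraction of gold
(variable, concept) pairs whose concept appears in the variable's top-k
list, plus the per-variable hit rank.

## Mapping sessions

A project binds one dictionary to one ontology and holds: visibility
(private by default; public projects accept mappings from any user), an ACL
with `can_map` (may map/unmap/comment) and `can_edit` (administrator level;
subsumes `can_map` and may grant privileges), the mapping set, per-variable
comment threads, and an append-only log. State transitions are strict:
mapping an already-mapped variable is an error (delete first), unmapping an
unmapped variable is an error. Any `can_map` holder may remove any mapping —
curation is collaborative and the log retains attribution. Replaying the
log's MAP/UNMAP events from an empty state reconstructs the live mapping set
exactly; this event-sourcing property is tested on randomized operation
sequences. Projects serialize to a versioned JSON file; timestamps are UTC
ISO 8601 and the clock is injectable for reproducible tests.

## Hierarchy branches

Each mapped concept is treated as a leaf and traced to every root it
reaches over all parent links. A branch is, per reached root, the set of
nodes lying on some root-to-mapped-concept path — equivalently, the
ancestors-or-self of the mapped set intersected with the descendants-or-self
of that root. Membership is deliberately **paths-only**: siblings or other
descendants of path nodes are excluded, keeping branch size proportional to
the mapping set rather than to the terminology (pulling in all children of
every path node would explode branches in a 150k-concept ontology).

Statistics are computed on the unique-member DAG: `node_count` is the
member count; `max_level` is the longest root-to-member path counted in
nodes (a single-node branch has level 1), obtained by a topological sweep.
For rendering, the DAG is expanded to a nested tree: children ordered by
(label, id); a member with several in-branch parents is duplicated under
each. Statistics never count duplicates. In adversarial stacked-diamond
DAGs this expansion is exponential; real is-a hierarchies are nearly
tree-like and branches are path-closures of small mapped sets, so this has
not been a practical concern — but it is a known limitation of the nested
format itself. Correctness is tested against exhaustive path-search oracles
(networkx reachability and DAG longest path) on random DAGs.

## CSV conventions

All files are RFC 4180, UTF-8 (BOM tolerated on read), header required;
multi-valued ontology cells use `|`. Ontology loading: rows with an empty
class id are skipped; on duplicate ids the last row wins (deterministic,
recoverable) — both are counted as warnings; parent references are matched
by exact string, values equal to a root marker (default `owl:Thing`) are
discarded, and references to concepts outside the export are dropped with a
warning count (the affected concept may become a root). Dictionary loading:
variable identity is an explicit id column when configured, otherwise the
variable name, with duplicate names disambiguated by `#2`, `#3`, …
suffixes. Variable search is plain case-insensitive substring — distinct
from the fuzzy concept recommendation on purpose, since keyword search is a
navigation aid, not a matcher.

The mapping export has the fixed header
`variable_id,variable_name,mapping_status,concept_id,concept_preferred_label,mapped_by,mapped_at,n_comments`,
one row per variable in dictionary order, LF line endings. Import applies
`M` rows whose variable and concept resolve and whose variable is unmapped;
it never overwrites (conflicts are skipped and reported), making import
idempotent and the export→import round trip lossless for the mapping set.
`n_comments` is informational only.

## Synthetic data generator

The generator emulates, at desk scale, a terminology plus a registry
dictionary derived from it: a random rooted tree (default fan-out ≤ 4,
depth ≤ 5) in which 5% of eligible nodes receive a second, strictly
shallower parent — exercising multi-parent paths while guaranteeing
acyclicity; distinct multi-word labels drawn from a bundled 255-word
biomedical vocabulary, constrained so that no label's token set contains
another's (this makes an unperturbed variable name have a unique
100-scoring concept, so planted-match recovery at zero noise is exact by
construction, not by luck); and variables created by copying sampled
concept labels with per-character edits (substitute/insert/delete, each
character edited with the stated probability) plus, with probability 0.3, an
appended numeric suffix token emulating "Race 1"-style registry variables.

A single `random.Random(seed)` drives everything; the same spec and seed
yield byte-identical CSVs. What the generator does **not** emulate: the
label-length and near-synonym distribution of a real 150k-concept
terminology, abbreviations and domain jargon ("Rx Summ", "Icd-O-3"), and
variables with no corresponding concept at all. Passing planted-match tests
therefore demonstrates correctness of the ranking machinery, not
real-world mapping accuracy — on the real task most variables have no
target (in the bundled expert sample only 47 of 301 registry variables had
one) and near-synonyms depress top-1 accuracy substantially.

## Packaged expert-verified sample

`data/table1_*.csv` bundle 47 cancer-registry variables with their
expert-verified terminology concepts: a gold list, a 47-variable dictionary,
a ready-to-import mapping-results CSV, and a flat fixture ontology holding
the 43 distinct target concepts (five "Race N" variables share one concept)
under synthesized stable ids `T1:C01`–`T1:C43`. The fixture ontology is
flat because the original hierarchy is the property of the full terminology;
branch behaviour is exercised on synthetic hierarchies instead.

## Parameter defaults

| Parameter | Default | Why |
|---|---|---|
| `k` (tracked candidates) | 10 | engine tracks ten; interfaces display about five |
| match field | preferred label | the terminology's canonical name; synonyms opt-in |
| visibility | private | safe default; public opt-in |
| root markers | `owl:Thing` | BioPortal exports mark top-level parents this way |
| multi-value separator | `\|` | BioPortal CSV convention |
| cross-parent rate (synthetic) | 0.05 | small multi-parent fraction, typical of is-a hierarchies |
| suffix probability (synthetic) | 0.3 | registry dictionaries number repeated fields |
| perturbation ops | sub/ins/del uniform | the three elementary edits, equally likely |

Problem sizes in the test suite and acceptance script (ontologies of
40–500 concepts, 12–40 planted variables, 20–100 seeds per property) were
chosen as the smallest scales at which the properties are non-trivial while
the whole suite stays interactive.

## Known limitations

- Everything is in memory; at 150k concepts recommendation is a linear scan
  (seconds per query), with no inverted index or embedding pre-filter.
- No OWL/OBO ingestion; CSV only. No authentication — users are plain
  identifiers, privileges are enforced per operation.
- Single-writer persistence (JSON project files); no concurrent-edit
  conflict resolution.
- The nested-tree expansion can repeat nodes (by design) and is exponential
  on adversarial DAGs.
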