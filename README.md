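# dictmap

Map **data-dictionary variables to ontology concepts** — the computational
core of an interactive terminology-mapping workflow, as a Python library and
a `dictmap` command-line tool.

Cancer registries and other data-collection efforts describe their variables
in data dictionaries (e.g. the NAACCR cancer-registry dictionary) that are
not ontological systems. Mapping those variables onto a reference terminology
such as the NCI Thesaurus (NCIt) enables semantic enrichment, harmonization
and faceted query of the collected data. Because dictionaries and ontologies
sit at different levels of semantic abstraction, the mapping is curated by
domain experts; software assists by recommending candidate concepts, keeping
an auditable record of decisions, and visualizing where the mapped concepts
sit in the target hierarchy.

`dictmap` covers that pipeline end to end:

- **Ontology library** — load BioPortal-dialect CSV exports (`Class ID`,
  `Preferred Label`, `Synonyms`, `Definitions`, `Parents`, `|`-separated
  multi-values), with field selection, dangling-parent cleanup, cycle
  detection, and hierarchy-root derivation.
- **Dictionaries** — load variable catalogues from CSV with configurable
  import/list/detail fields; browse and keyword search.
- **Recommendation engine** — score every concept against a variable and
  return the top *k* (default 10) candidates.  The score of two texts
  $a, b$ (normalized: NFKC, lower case, punctuation → space) is

  $$s(a,b) = \max\bigl(\mathrm{ratio}(a,b),\; \mathrm{tsr}(a,b)\bigr), \qquad
  \mathrm{ratio}(x,y) = 100\Bigl(1 - \frac{\mathrm{lev}(x,y)}{\max(|x|,|y|)}\Bigr)$$

  where `lev` is the Levenshtein edit distance and `tsr` is the token-set
  ratio: with $t_a, t_b$ the sorted unique token sets,
  $i = t_a \cap t_b$, $u_a = i \cup (t_a \setminus t_b)$,
  $u_b = i \cup (t_b \setminus t_a)$ rendered as space-joined strings,
  $\mathrm{tsr} = \max(\mathrm{ratio}(i,u_a), \mathrm{ratio}(i,u_b),
  \mathrm{ratio}(u_a,u_b))$.  The full ratio captures character-level edit
  noise ("Ruralurban" vs "Rural-Urban"); the token-set ratio scores 100 for
  word-order changes and token subsets ("Race 1" vs "Race").
- **Mapping sessions** — projects binding a dictionary to a target ontology,
  with public/private visibility, `can_edit`/`can_map` privileges, one
  mapped concept per variable (M/U status), comment threads, and an
  append-only audit log that replays to the exact mapping state.
- **Hierarchy branches** — treat each mapped concept as a leaf, trace all
  parent paths to the hierarchy roots, and emit one branch per reached root
  with node count and maximum level, plus a nested-tree JSON for renderers
  (multi-parent members are duplicated per parent in the rendering only).
- **Interchange** — export the mapping set to CSV and re-import it
  losslessly; imports never overwrite existing mappings.
- **Synthetic data** — seeded random ontologies plus dictionaries whose
  variable names are perturbed concept labels with planted ground truth, and
  a packaged expert-verified sample of 47 cancer-registry variables mapped
  onto 43 terminology concepts.

## Worked example

```python
import dictmap as dm

fx = dm.load_table1_fixture()          # packaged expert-verified sample
var = fx.dictionary.get_variable("Date Of Birth")
for r in dm.recommend_top_k(var, fx.ontology, k=10)[:5]:
    print(f"{r.rank:2d}. {r.score:6.1f}  {r.label}  ({r.concept_id})")
```

```
 1.  100.0  Birth Date  (T1:C06)
 2.   57.1  Cause of Death  (T1:C14)
 3.   53.8  Date of Last Contact  (T1:C09)
 4.   50.0  Birth Country Code  (T1:C08)
 5.   50.0  Birth State Code  (T1:C07)
```

"Date Of Birth" and "Birth Date" share the token set `{birth, date}`, so the
token-set ratio is 100 and the verified concept ranks first; the remaining
candidates score by partial token overlap. Evaluating the engine against the
whole packaged gold set:

```python
report = dm.top_k_accuracy(fx.gold, fx.ontology, k=1)
print(report.n_hits, "/", report.n_pairs)   # 45 / 47
```

45 of the 47 expert-verified pairs are recovered at rank 1 (46 within the
top five) when matching against the small 43-concept fixture ontology.
Against a full terminology with ~150,000 concepts, accuracy is necessarily
much lower because thousands of near-synonymous labels compete — see the
methods note.

The same workflow from the shell:

```bash
dictmap simulate --concepts 40 --perturb 0.05 --seed 3 --out sim
dictmap ontology add --csv sim/ontology.csv --name demo-onto
dictmap dict add --csv sim/dictionary.csv --name demo-dict --name-field Variable
dictmap project create --name demo --ontology demo-onto --dict demo-dict --owner alice
dictmap recommend --project demo --variable "Transfer Summaryp Health"
dictmap map --project demo --variable "Transfer Summaryp Health" --concept SYN:0015 --as alice
dictmap status --project demo
dictmap branches --project demo --out viz        # nested-tree JSON + stats CSV
dictmap export --project demo --out mappings.csv
```

Exit codes: 0 success, 1 validation/config, 2 I/O, 3 permission, 4 illegal
mapping state.

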