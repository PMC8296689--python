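# ontoxref

Atomic cross-referencing of disease ontologies, and transitive queries over
their merged hierarchies — without a graph database.

## The problem

Biomedical data sources disagree about how to name diseases: MONDO, MeSH,
UMLS, EFO, NCIT, OMIM, DOID, Orphanet, HP and ICD-10 each carry their own
identifiers *and* their own is_a hierarchy. Integrating data therefore means
answering three recurring questions: which terms across ontologies denote
the same disease, what are all sub-classes of a disease regardless of which
hierarchy asserts them, and how does one ontology's term set look when
projected onto another ontology's hierarchy. `ontoxref` answers all three
for bioinformaticians building knowledge graphs or harmonising annotations.

## The model

An ontological matching is a triple *m* = ⟨*t_id*, *t_j*, *s*⟩ with binary
similarity *s* ∈ {0, 1}, where *t_id* is the preferred disease term (MONDO
by default, configurable) and *t_j* a term of another ontology; only exact
matches are kept, so every materialised matching has *s* = 1. An atomic
mapping is the pair μ = ⟨*t_id*, *t_j*⟩ — one preferred term paired with at
most one term per other ontology. A disease cluster is one preferred term
plus all of its atomic mappings; serialised, it is one row of a
cross-reference flat file that curators can edit directly.

Cluster evidence comes from the preferred term's own xrefs (direct), other
terms' xrefs pointing at it (reverse), and one-hop bridges through a hub
ontology — UMLS — for ontologies such as NCIT that are cross-referenced
through UMLS alone. Two defect classes are detected and repaired on the
xref layer before clustering: references to obsolete terms (followed to
their `replaced_by` replacement, or dropped), and multilevel references —
a term referencing *b* together with children *b₁ … bₙ* of *b* — collapsed
to *b* alone, since they are valid but not atomic. Conflicts that cannot be
repaired automatically (two unrelated candidates of one namespace) are
excluded and reported for curation rather than guessed.

The clusters then become nodes of a merged graph whose edges are every
source ontology's is_a assertions, labelled by ontology and never
collapsed. Sub-class / super-class queries are plain reachability over any
chosen subset of hierarchies, a term can be looked up by any of its
ontology ids, and a viewpoint projection restricted to one ontology's
edges reproduces exactly that ontology's own subtree.

## Worked example

The record for chronic kidney disease: MONDO_0005300 cross-references six
other ontologies.

```python
from ontoxref import extract_matchings, parse_obo_subset

CKD = """\
[Term]
id: MONDO:0005300
name: chronic kidney disease
xref: MeSH:D007676
xref: UMLS:C0022661
xref: EFO:EFO_0003884
xref: NCIT:C80078
xref: DOID:784
xref: ICD10:N18.9
"""

mondo = parse_obo_subset(CKD, "MONDO")
build = extract_matchings({"MONDO": mondo})
cluster = build.clusters[0]
print(len(build.clusters), len(cluster.atomic_mappings()), len(build.matchings))
print(cluster.members)
```

prints

```
1 6 6
{'DOID': 'DOID_784', 'EFO': 'EFO_0003884', 'ICD10': 'N18.9',
 'MESH': 'D007676', 'NCIT': 'NCIT_C80078', 'UMLS': 'C0022661'}
```

one cluster, six atomic mappings, six matching triples with *s* = 1: each
xref spelling has been normalised (`MeSH:D007676` → MESH / `D007676`,
`NCIT:C80078` → NCIT / `NCIT_C80078`) and admitted as exactly one member
per namespace.

The same pipeline from the shell, end to end on a synthetic ontology set:

```
ontoxref fixture -o fx --size 50 --n-ontologies 5 --retention 0.8 --seed 1
ontoxref build -i fx -o out
ontoxref subclasses -i fx MONDO_0000000 --scope ALL
ontoxref remap -i fx --from MESH --to MONDO
ontoxref stats -i fx
```

`build` writes `cross-reference.tsv` (one row per disease cluster),
`merged-edges.tsv` / `merged-nodes.tsv` (the labelled union graph) and
`curation-report.tsv` (unrepaired discrepancies and atomicity conflicts).
`subclasses` prints every transitive descendant of the given term across
the in-scope hierarchies; `remap` reports for each MeSH term its MONDO
equivalent (MAPPED), its nearest MONDO-bearing ancestors
(PLACED_BY_ANCESTOR), or UNMAPPED; `stats` prints the per-ontology
contribution table (terms only in this ontology, preferred terms,
references, unique references).

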