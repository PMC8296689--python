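# Methods

## Matching model

A matching is a triple ⟨*t_id*, *t_j*, *s*⟩ with *s* ∈ {0, 1}; an atomic
mapping is the pair ⟨*t_id*, *t_j*⟩. Only exact equivalences are
considered — close or lexical matches are out of scope by design — so
similarity-0 triples carry no information and are never materialised: a
pair's absence *is* the zero. The atomicity principle is the one invariant
the whole pipeline protects: a disease cluster holds at most one term per
ontology. Everything else (which ontology is preferred, which evidence
sources are used, which namespaces participate) is configuration.

## Cluster extraction

Every non-obsolete term of the head preference namespace (default MONDO,
because it cross-references the most other ontologies) seeds a cluster.
Membership evidence is applied in three tiers:

1. **direct** — the preferred term's own xrefs;
2. **reverse** — xrefs of other ontologies' terms that point at the
   preferred term;
3. **hub-bridged** — exactly one hop through a hub namespace (default
   UMLS): if the cluster already holds hub term *u* and term *x* elsewhere
   references *u* (or *u* references *x*), *x* joins.

Terms left in no cluster then seed their own, walking the preference
order, so every cluster's preferred term is the first preference-order
namespace it contains. The evidence mode is flag-selectable
(`direct`, `direct+reverse`, `direct+reverse+hub`; default all three)
because real pipelines differ in how much they trust reverse assertions.

Design choices that were genuinely open:

* **Hub depth is exactly one hop.** Unlimited chaining through a
  thesaurus-scale hub would merge distinct diseases; one hop covers the
  ontologies whose only cross-referencing source is UMLS.
* **Conflicts admit neither candidate.** When two distinct terms of one
  namespace are proposed for one cluster, the default policy records both
  for curation and admits none (`--keep-first` opts into keeping the
  best-evidenced, smallest-id candidate). Automatic tie-breaking would
  silently prefer one ontology's opinion.
* **A term that is a cluster's preferred identity is never admitted as a
  member of another cluster.** Without this rule a one-directional xref
  would represent the same disease twice — once as a cluster, once as a
  member — and term lookup in the merged graph would become ambiguous.
  Plain xref *targets* may still appear in many clusters (many-to-one is
  real: coarse ICD-10 codes are referenced by many finer terms); the
  restriction applies only to cluster identities.
* **Many-to-one is allowed across clusters, atomicity is per cluster.**

Extraction is invariant under permutation of the input ontology
collection: processing order is fixed by the configured namespace order
and lexicographic term ids, never by input order.

## Discrepancy detection and repair

Two defect classes occur in the wild and are handled before clustering:

* **Obsolete target** — an xref whose target term is flagged obsolete.
  Repair follows the `replaced_by` chain to a live term (with a cycle
  guard) and redirects the xref; if no live replacement exists the xref is
  dropped.
* **Multilevel reference** — a term referencing *b* together with
  descendants of *b* in one namespace: correct from the source's point of
  view, but not atomic. When one referenced target is a strict ancestor of
  every other referenced target, the group collapses to that ancestor.
  Only the *referenced* set is examined; inferring an unreferenced common
  ancestor would be close matching. Multi-target groups with no such
  common referenced ancestor are reported unrepaired — note this makes an
  unrelated-duplicate reference (an atomicity conflict) a special case of
  the unrepaired multilevel group, which is intended: both surface in the
  same curation report.

Repairs are applied to a copy of the in-memory xref layer; source
ontology files are never modified. Detect-and-repair is idempotent: a
second pass finds only the unrepaired set and changes nothing.

## Merged graph and queries

One node per cluster, carrying the cluster's full per-ontology attribute
map; one child → parent edge per source-ontology is_a assertion whose two
endpoint terms both belong to clusters. Parallel edges are kept per source
ontology rather than collapsed, which is what makes scope-restricted
queries and provenance display possible. Descendant/ancestor queries are
visited-set reachability over the edges whose label is in scope;
non-reflexive by default (`include_self` flips it). A query root may be
given in any namespace — an ICD-10 code resolves to the same node as its
MONDO twin — and ambiguous ids (attributed to several nodes) raise rather
than guess.

Per-ontology subgraphs are acyclic whenever their source is, but the
cross-ontology union may contain cycles where two ontologies disagree on
direction. Cycles are detected (elementary-cycle enumeration, capped,
deduplicated across parallel-edge variants) and reported with per-step
edge labels so curators can see which pair disagrees; no edge is deleted
to break them, since any deletion rule would silently prefer one ontology.

Remapping source namespace → target namespace classifies every
source-bearing node: MAPPED on cluster co-membership; otherwise
PLACED_BY_ANCESTOR with the *nearest* target-bearing ancestors — the
minimal antichain of the ancestor set, keeping incomparable ties sorted
rather than picking one; otherwise UNMAPPED. The counts conserve: the
three statuses sum to the number of source-bearing nodes.

## Contribution statistics

The per-ontology table reports terms only in this ontology (singleton
clusters), preferred terms, references (preferred appearances plus
memberships) and unique references (distinct local ids). Whether
"preferred terms" should include singleton-only clusters is ambiguous, so
both breakdowns are reported (`preferred_terms`, inclusive — its total
equals the cluster count — and `preferred_terms_excl_only`). Totals
conserve: total references equal Σ over clusters of (1 + member count).

## Synthetic fixtures

The generator emulates the one real-world structure the pipeline relies
on: several ontologies as differently granular views of one disease
landscape. A random rooted master tree of "true diseases" is drawn (each
node picks an earlier node as parent); each derived ontology keeps each
master node with retention probability *p* and contracts hierarchy edges
through dropped nodes (grandparent rewiring), producing coarser and finer
hierarchies — which is exactly how multilevel references arise naturally.
Cross-references are planted at density *d*: the first-present ontology's
term stars its co-derived terms mutually, non-head terms additionally
reference the UMLS term, and NCIT is emulated as in the wild —
cross-referenced solely through UMLS, joinable only over the hub bridge.
Defaults are retention 0.8, density 1.0, four ontologies, a 50-node master
tree: overlapping-but-not-identical coverage with complete cross-
referencing, which is the modern situation for the major disease
ontologies. Namespace order matches the pipeline's preference fallback so
planted group heads coincide with extraction's preferred terms.

Planted defects record their ground truth exactly: obsolete-target
references (a planted obsolete term with `replaced_by` pointing back at
the real target), multilevel references (added child xrefs under a
referenced parent), atomicity conflicts (a stray reference to a
hierarchically unrelated term; never targeting the hub namespace, where a
stray hub reference would be legitimate bridge evidence rather than a
defect, and never to a term that is itself a cluster identity), and
cross-ontology cycle pairs (one hierarchy edge flipped in the last
ontology — which later plants then avoid as a target). Defect categories
use disjoint master nodes so detector output is comparable to the plant
list set-for-set. Everything is driven by one seed; a fixed seed yields
byte-identical files.

What the fixtures do **not** emulate: lexical variation in labels,
partial/asymmetric xref coverage within one record, close-match xrefs,
multi-parent source hierarchies (each derived hierarchy is a contracted
tree, though the *merged* graph is a multi-DAG), and the sheer scale and
messiness of real 2020s ontology snapshots. Passing tests therefore show
the algorithms are correct under the stated model, not that any particular
real-world record count would be reproduced.

## Numerical and procedural choices

* Identifier canonical form: OBO-style namespaces embed their prefix
  (`DOID:784` → `DOID_784`, `NCIT:C80078` → `NCIT_C80078`); MeSH, UMLS,
  OMIM and ICD-10 keep native codes. Prefix spellings are normalised by a
  fixed alias table; unknown prefixes are preserved under `UNKNOWN` and
  excluded from matching. Normalisation is lossless (raw text retained).
* ICD-10 synthetic fixtures use flat alphanumeric codes over the shared
  master tree; the hierarchy TSV dialect treats any parent list as is_a,
  so chapter/block nesting is representable but not specially encoded.
* Obsolete terms are parsed but excluded from hierarchy reasoning and
  cluster membership; they exist only as repair targets.
* Cyclic source hierarchies: parsing succeeds, validation reports, and
  downstream builders refuse them unless `--force` is given.
* All serialisations are deterministically ordered (lexicographic by id),
  making round-trip identity and byte-level reproducibility testable.
* Cycle enumeration is capped (default 1000) — union graphs of
  disagreeing ontologies can in principle hold many elementary cycles.
* Test problem sizes: the query-oracle battery uses 100 random fixtures of
  up to ~200 nodes against a brute-force fixpoint closure; exact-recovery
  checks run up to 10 ontologies × 500 master nodes. These sizes give full
  structural coverage (all evidence tiers, contraction, all defect
  classes) while keeping the suite fast to iterate on.

## Known limitations

* No lexical or probabilistic fallback for UNMAPPED terms — deliberate,
  but it means coverage against a poorly cross-referenced ontology is low.
* Hub bridging trusts the hub's identity assertions; a wrong UMLS CUI
  merge propagates (one hop deep at most).
* The flat file stores no provenance column, so evidence tags
  (direct/reverse/hub) survive in the curation report but not through a
  write/read round trip.
* Contribution statistics describe the loaded snapshot only; they are not
  comparable across differently configured namespace sets.
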