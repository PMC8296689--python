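"""Synthetic multi-ontology fixtures with planted ground truth.

Real disease ontologies are overlapping, differently granular views of one
underlying disease landscape.  The generator emulates that: it draws a
random rooted master tree of "true diseases", derives each ontology by
keeping every master node with a retention probability and contracting
hierarchy edges through dropped nodes (grandparent rewiring), and plants
exact-match xrefs between co-derived terms at a configurable density.  The
first-present ontology's term for a disease cross-references every other
co-derived term mutually, and non-head terms additionally reference the
UMLS term when one exists.  NCIT is emulated as it occurs in the wild:
cross-referenced solely through UMLS, so NCIT terms can join a cluster only
over the hub bridge — the generator exercises all three evidence tiers
(direct, reverse, hub-bridged).

Defects can be planted on top, each recorded in the ground truth:

* obsolete-target references (the xref is redirected to a planted obsolete
  term whose ``replaced_by`` points back at the real target),
* multilevel references (the source additionally references children of its
  target — well-formed but non-atomic),
* atomicity conflicts (the source references a second, hierarchically
  unrelated term of the same namespace; by construction these are also
  unrepairable multilevel groups),
* cross-ontology cycle pairs (one hierarchy edge is flipped in the last
  ontology, so the merged union disagrees on direction).

Everything is driven by one seed: a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from random import Random
from typing import Callable

from .model import Ontology, OntologyTerm, TermRef, normalize_xref

__all__ = [
    "FIXTURE_NAMESPACES",
    "FixtureSpec",
    "GroundTruth",
    "FixtureSet",
    "generate_fixture",
    "write_fixture",
]

#: Namespaces assigned to derived ontologies, in order: the configured
#: default namespace order, so a fixture's first-present ontology for any
#: disease coincides with the extraction pipeline's preferred-term fallback.
FIXTURE_NAMESPACES: tuple[str, ...] = (
    "MONDO", "MESH", "UMLS", "EFO", "NCIT",
    "OMIM", "DOID", "ORPHANET", "HP", "ICD10",
)

#: Namespaces cross-referenced exclusively through UMLS (as NCIT is in the
#: wild): their terms carry only a UMLS xref and nobody references them
#: directly, so they can join a cluster only over the hub bridge.
HUB_ONLY_NAMESPACES: frozenset[str] = frozenset({"NCIT"})

_ID_SCHEMES: dict[str, Callable[[int], str]] = {
    "MONDO": lambda i: f"MONDO_{i:07d}",
    "UMLS": lambda i: f"C{i:07d}",
    "MESH": lambda i: f"D{i:06d}",
    "EFO": lambda i: f"EFO_{i:07d}",
    "NCIT": lambda i: f"NCIT_C{i:06d}",
    "DOID": lambda i: f"DOID_{i:06d}",
    "ORPHANET": lambda i: f"ORPHANET_{i:06d}",
    "HP": lambda i: f"HP_{i:07d}",
    "ICD10": lambda i: f"Z{i:05d}",
    "OMIM": lambda i: f"{600000 + i}",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    master_tree_size: int = 50
    n_ontologies: int = 4
    retention: float = 0.8
    xref_density: float = 1.0
    n_obsolete_refs: int = 0
    n_multilevel_refs: int = 0
    n_conflicts: int = 0
    n_cycle_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.master_tree_size < 1:
            raise ValueError("master_tree_size must be >= 1")
        if not 1 <= self.n_ontologies <= len(FIXTURE_NAMESPACES):
            raise ValueError(
                f"n_ontologies must be in 1..{len(FIXTURE_NAMESPACES)}"
            )
        for name in ("retention", "xref_density"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        for name in (
            "n_obsolete_refs", "n_multilevel_refs", "n_conflicts", "n_cycle_pairs"
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def namespaces(self) -> tuple[str, ...]:
        return FIXTURE_NAMESPACES[: self.n_ontologies]


@dataclass(frozen=True)
class ObsoletePlant:
    source: TermRef
    obsolete_target: TermRef
    replacement: TermRef


@dataclass(frozen=True)
class MultilevelPlant:
    source: TermRef
    parent_target: TermRef
    child_targets: tuple[TermRef, ...]


@dataclass(frozen=True)
class ConflictPlant:
    source: TermRef
    namespace: str
    candidates: tuple[str, ...]


@dataclass(frozen=True)
class CyclePlant:
    child_master: int
    parent_master: int
    forward_ontology: str   # asserts child is_a parent
    flipped_ontology: str   # asserts parent is_a child


@dataclass
class GroundTruth:
    """Everything planted into a fixture, for exact recovery checks."""

    groups: list[frozenset[TermRef]] = field(default_factory=list)
    master_edges: list[tuple[int, int]] = field(default_factory=list)
    obsolete_refs: list[ObsoletePlant] = field(default_factory=list)
    multilevel_refs: list[MultilevelPlant] = field(default_factory=list)
    conflicts: list[ConflictPlant] = field(default_factory=list)
    cycle_pairs: list[CyclePlant] = field(default_factory=list)

    def to_json(self) -> str:
        def ref(r: TermRef) -> list[str]:
            return [r.ontology, r.local_id]

        payload = {
            "groups": [sorted(map(ref, g)) for g in self.groups],
            "master_edges": self.master_edges,
            "obsolete_refs": [
                {
                    "source": ref(p.source),
                    "obsolete_target": ref(p.obsolete_target),
                    "replacement": ref(p.replacement),
                }
                for p in self.obsolete_refs
            ],
            "multilevel_refs": [
                {
                    "source": ref(p.source),
                    "parent_target": ref(p.parent_target),
                    "child_targets": [ref(c) for c in p.child_targets],
                }
                for p in self.multilevel_refs
            ],
            "conflicts": [
                {
                    "source": ref(p.source),
                    "namespace": p.namespace,
                    "candidates": list(p.candidates),
                }
                for p in self.conflicts
            ],
            "cycle_pairs": [asdict(p) for p in self.cycle_pairs],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class FixtureSet:
    spec: FixtureSpec
    ontologies: dict[str, Ontology]
    truth: GroundTruth


def _nearest_kept_ancestor(
    node: int, parent_of: dict[int, int], kept: set[int]
) -> int | None:
    current = parent_of.get(node)
    while current is not None and current not in kept:
        current = parent_of.get(current)
    return current


def generate_fixture(spec: FixtureSpec) -> FixtureSet:
    """Generate K derived ontologies plus ground truth, deterministically."""
    rng = Random(spec.seed)
    size = spec.master_tree_size
    namespaces = spec.namespaces

    # master tree: node 0 is the root, every later node picks an earlier parent
    parent_of: dict[int, int] = {
        i: rng.randrange(i) for i in range(1, size)
    }
    truth = GroundTruth(master_edges=sorted(parent_of.items()))

    # per-ontology retention + contracted hierarchies
    kept: dict[str, set[int]] = {}
    for ns in namespaces:
        kept[ns] = {
            i for i in range(size) if spec.retention >= 1.0 or rng.random() < spec.retention
        }

    ontologies: dict[str, Ontology] = {}
    ids: dict[str, dict[int, str]] = {}
    for ns in namespaces:
        scheme = _ID_SCHEMES[ns]
        ontology = Ontology(namespace=ns, version_tag=f"synthetic-seed-{spec.seed}")
        ids[ns] = {}
        for i in sorted(kept[ns]):
            local_id = scheme(i)
            ids[ns][i] = local_id
            anc = _nearest_kept_ancestor(i, parent_of, kept[ns])
            ontology.add(
                OntologyTerm(
                    ontology=ns,
                    local_id=local_id,
                    label=f"disease {i:05d}",
                    parents={scheme(anc)} if anc is not None else set(),
                )
            )
        ontologies[ns] = ontology

    def term_ref(ns: str, master: int) -> TermRef:
        return TermRef(ns, ids[ns][master])

    def add_xref(source: TermRef, target: TermRef) -> None:
        raw = f"{target.ontology}:{target.local_id}"
        ontologies[source.ontology].terms[source.local_id].xrefs.add(
            normalize_xref(raw)
        )

    # co-reference groups + planted xrefs: the first-present ontology stars
    # the other co-derived terms (mutually), except hub-only namespaces,
    # which are linked solely through their UMLS spoke
    for i in range(size):
        present = [ns for ns in namespaces if i in kept[ns]]
        if not present:
            continue
        truth.groups.append(frozenset(term_ref(ns, i) for ns in present))
        head = present[0]

        def dense() -> bool:
            return spec.xref_density >= 1.0 or rng.random() < spec.xref_density

        for other in present[1:]:
            if other in HUB_ONLY_NAMESPACES and head != "UMLS":
                continue  # reachable through the UMLS spoke only
            if dense():
                add_xref(term_ref(head, i), term_ref(other, i))
            if dense():
                add_xref(term_ref(other, i), term_ref(head, i))
        if "UMLS" in present and head != "UMLS":
            for other in present:
                if other in (head, "UMLS"):
                    continue
                if dense():
                    add_xref(term_ref(other, i), term_ref("UMLS", i))

    _plant_defects(spec, rng, ontologies, ids, kept, parent_of, truth)
    return FixtureSet(spec=spec, ontologies=ontologies, truth=truth)


def _plant_defects(spec, rng, ontologies, ids, kept, parent_of, truth) -> None:
    namespaces = spec.namespaces
    size = spec.master_tree_size

    def present_at(i: int) -> list[str]:
        return [ns for ns in namespaces if i in kept[ns]]

    def master_ancestors(i: int) -> set[int]:
        out = set()
        current = parent_of.get(i)
        while current is not None:
            out.add(current)
            current = parent_of.get(current)
        return out

    # cycle pairs first: they flip edges in the LAST namespace, which the
    # later defect planters then avoid as a target, keeping ground truth exact
    flipped_ns: str | None = None
    if spec.n_cycle_pairs:
        if spec.n_ontologies < 2:
            raise ValueError("cycle pairs need at least two ontologies")
        ns_a, ns_b = namespaces[0], namespaces[-1]
        flipped_ns = ns_b
        shared = [
            (child, parent)
            for child, parent in sorted(parent_of.items())
            if child in kept[ns_a] and parent in kept[ns_a]
            and child in kept[ns_b] and parent in kept[ns_b]
            and ontologies[ns_b].terms[ids[ns_b][child]].parents == {ids[ns_b][parent]}
        ]
        if len(shared) < spec.n_cycle_pairs:
            raise ValueError(
                f"cannot plant {spec.n_cycle_pairs} cycle pair(s); "
                f"only {len(shared)} shared edges available"
            )
        for child, parent in rng.sample(shared, spec.n_cycle_pairs):
            child_term = ontologies[ns_b].terms[ids[ns_b][child]]
            parent_term = ontologies[ns_b].terms[ids[ns_b][parent]]
            child_term.parents.discard(ids[ns_b][parent])
            parent_term.parents.add(ids[ns_b][child])
            truth.cycle_pairs.append(
                CyclePlant(
                    child_master=child,
                    parent_master=parent,
                    forward_ontology=ns_a,
                    flipped_ontology=ns_b,
                )
            )

    used_masters: set[int] = set()

    def target_choices(i: int) -> list[str]:
        present = present_at(i)
        if len(present) < 2:
            return []
        return [ns for ns in present[1:] if ns != flipped_ns]

    def add_xref(source: TermRef, target: TermRef) -> None:
        raw = f"{target.ontology}:{target.local_id}"
        ontologies[source.ontology].terms[source.local_id].xrefs.add(
            normalize_xref(raw)
        )

    def drop_xref(source: TermRef, target: TermRef) -> None:
        term = ontologies[source.ontology].terms[source.local_id]
        term.xrefs = {x for x in term.xrefs if x.target != target}

    # obsolete-target references
    if spec.n_obsolete_refs:
        eligible = [
            i for i in range(size)
            if i not in used_masters and target_choices(i)
        ]
        if len(eligible) < spec.n_obsolete_refs:
            raise ValueError("not enough eligible masters for obsolete plants")
        for k, i in enumerate(rng.sample(eligible, spec.n_obsolete_refs)):
            used_masters.add(i)
            head = present_at(i)[0]
            target_ns = rng.choice(target_choices(i))
            real = TermRef(target_ns, ids[target_ns][i])
            obsolete_id = _ID_SCHEMES[target_ns](size + k)
            ontologies[target_ns].add(
                OntologyTerm(
                    ontology=target_ns,
                    local_id=obsolete_id,
                    label=f"obsolete disease {i:05d}",
                    obsolete=True,
                    replaced_by=real.local_id,
                )
            )
            source = TermRef(head, ids[head][i])
            drop_xref(source, real)
            add_xref(source, TermRef(target_ns, obsolete_id))
            truth.obsolete_refs.append(
                ObsoletePlant(
                    source=source,
                    obsolete_target=TermRef(target_ns, obsolete_id),
                    replacement=real,
                )
            )

    # multilevel references: head also references children of its target
    if spec.n_multilevel_refs:
        children_of: dict[str, dict[int, list[int]]] = {}
        for ns in namespaces:
            children_of[ns] = {}
            for child in kept[ns]:
                anc = _nearest_kept_ancestor(child, parent_of, kept[ns])
                if anc is not None:
                    children_of[ns].setdefault(anc, []).append(child)
        eligible = []
        for i in range(size):
            if i in used_masters:
                continue
            for ns in target_choices(i):
                if children_of[ns].get(i):
                    eligible.append((i, ns))
                    break
        if len(eligible) < spec.n_multilevel_refs:
            raise ValueError("not enough eligible masters for multilevel plants")
        for i, target_ns in rng.sample(eligible, spec.n_multilevel_refs):
            used_masters.add(i)
            head = present_at(i)[0]
            source = TermRef(head, ids[head][i])
            parent_target = TermRef(target_ns, ids[target_ns][i])
            add_xref(source, parent_target)  # ensure b itself is referenced
            child_masters = sorted(children_of[target_ns][i])[:2]
            child_refs = tuple(
                TermRef(target_ns, ids[target_ns][c]) for c in child_masters
            )
            for ref in child_refs:
                add_xref(source, ref)
            truth.multilevel_refs.append(
                MultilevelPlant(
                    source=source,
                    parent_target=parent_target,
                    child_targets=child_refs,
                )
            )

    # atomicity conflicts: a second, hierarchically unrelated same-namespace
    # target (also an unrepairable multilevel group by definition).  Hub
    # namespaces are excluded as targets: a stray reference to a hub term
    # would legitimately bridge the source into the partner's cluster,
    # which is hub semantics, not an atomicity defect.
    if spec.n_conflicts:
        eligible = []
        for i in range(size):
            if i in used_masters:
                continue
            for ns in (n for n in target_choices(i) if n != "UMLS"):
                partners = [
                    j for j in sorted(kept[ns])
                    if j != i and j not in used_masters
                    and j not in master_ancestors(i)
                    and i not in master_ancestors(j)
                    # the stray term must not be a cluster identity itself,
                    # or the conflict could never surface as a membership
                    and present_at(j)[0] != ns
                ]
                if partners:
                    eligible.append((i, ns, partners))
                    break
        if len(eligible) < spec.n_conflicts:
            raise ValueError("not enough eligible masters for conflict plants")
        for i, target_ns, partners in rng.sample(eligible, spec.n_conflicts):
            j = rng.choice(partners)
            used_masters.update((i, j))
            head = present_at(i)[0]
            source = TermRef(head, ids[head][i])
            own = TermRef(target_ns, ids[target_ns][i])
            add_xref(source, own)  # ensure the legitimate target is present
            stray = TermRef(target_ns, ids[target_ns][j])
            add_xref(source, stray)
            truth.conflicts.append(
                ConflictPlant(
                    source=source,
                    namespace=target_ns,
                    candidates=tuple(sorted((own.local_id, stray.local_id))),
                )
            )


def write_fixture(fixture: FixtureSet, directory: str | Path) -> list[Path]:
    """Write one hierarchy TSV per ontology plus the ground-truth JSON."""
    from .model import write_hierarchy_tsv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for ns in sorted(fixture.ontologies):
        path = directory / f"{ns}.tsv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            write_hierarchy_tsv(fixture.ontologies[ns], fh)
        written.append(path)
    truth_path = directory / "ground_truth.json"
    truth_path.write_text(fixture.truth.to_json() + "\n", encoding="utf-8")
    written.append(truth_path)
    return written
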