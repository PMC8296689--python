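"""Atomic ontological matching across disease ontologies.

The matching formalism: a matching is a triple ``m = <t_id, t_j, s>`` where
``t_id`` is the preferred disease term, ``t_j`` a term of another ontology
and ``s`` a binary similarity degree.  Only exact matches are considered, so
every materialised matching has ``s = 1``; zero-similarity triples are
implicit and never stored.  An atomic mapping is the pair ``mu = <t_id,
t_j>`` — one preferred term paired with at most one term per other ontology.
A :class:`DiseaseCluster` groups one preferred term with all of its atomic
mappings; one cluster is one row of the cross-reference flat file.

Cluster evidence comes from three sources, in order:

direct
    xrefs asserted by the preferred term itself.
reverse
    xrefs of other ontologies' terms pointing at the preferred term.
hub-bridged
    one hop through a hub namespace (UMLS by default): if the cluster
    already holds hub term ``u`` and ontology X term ``x`` also references
    ``u``, ``x`` joins the cluster.

Two discrepancy kinds are detected and repaired on the xref layer only
(source ontologies are never modified): references to obsolete targets
(followed to their ``replaced_by`` replacement, or dropped), and multilevel
references — a term referencing another ontology's term ``b`` together with
descendants of ``b`` — collapsed to ``b`` alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx

from .model import (
    DEFAULT_NAMESPACES,
    Ontology,
    RawXref,
    TermRef,
    validate_ontology,
)

__all__ = [
    "Matching",
    "AtomicMapping",
    "DiseaseCluster",
    "Discrepancy",
    "DiscrepancyKind",
    "MatchingBuild",
    "RepairAction",
    "CyclicHierarchyError",
    "ConfigurationError",
    "extract_matchings",
    "detect_obsolete_refs",
    "detect_multilevel_refs",
    "repair_matchings",
    "validate_atomicity",
    "write_xref_tsv",
    "read_xref_tsv",
    "write_curation_report",
    "contribution_stats",
]

logger = logging.getLogger(__name__)

EVIDENCE_MODES = ("direct", "direct+reverse", "direct+reverse+hub")


class ConfigurationError(ValueError):
    """Unknown namespace or otherwise invalid pipeline configuration."""


class CyclicHierarchyError(ValueError):
    """A source hierarchy contains an is_a cycle and force was not given."""


@dataclass(frozen=True, order=True)
class Matching:
    """The matching triple <t_id, t_j, s> with binary similarity s."""

    t_id: TermRef
    t_j: TermRef
    s: int = 1

    def __post_init__(self) -> None:
        if self.s not in (0, 1):
            raise ValueError(f"similarity degree must be 0 or 1, got {self.s!r}")
        if self.t_id.ontology == self.t_j.ontology:
            raise ValueError("a matching pairs terms of two different ontologies")


@dataclass(frozen=True, order=True)
class AtomicMapping:
    """The atomic pair mu = <t_id, t_j> (a matching with s = 1)."""

    t_id: TermRef
    t_j: TermRef


@dataclass
class DiseaseCluster:
    """One disease: a preferred term plus <=1 matched term per namespace.

    ``provenance`` tags each member with its evidence source and ``conflicts``
    records namespaces where atomicity failed (>=2 candidates, none admitted
    under the default policy); neither takes part in equality, mirroring the
    flat-file columns.
    """

    preferred: TermRef
    label: str
    members: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict, compare=False)
    conflicts: dict[str, list[str]] = field(default_factory=dict, compare=False)

    def member_refs(self) -> list[TermRef]:
        return [TermRef(ns, lid) for ns, lid in sorted(self.members.items())]

    def attributes(self) -> dict[str, str]:
        """All ontology attributes of the disease node: members + preferred."""
        attrs = dict(self.members)
        attrs[self.preferred.ontology] = self.preferred.local_id
        return attrs

    def matchings(self) -> list[Matching]:
        return [Matching(self.preferred, ref, 1) for ref in self.member_refs()]

    def atomic_mappings(self) -> list[AtomicMapping]:
        return [AtomicMapping(self.preferred, ref) for ref in self.member_refs()]


class DiscrepancyKind(str, Enum):
    OBSOLETE_TARGET = "OBSOLETE_TARGET"
    MULTILEVEL = "MULTILEVEL"


@dataclass(frozen=True)
class Discrepancy:
    """A detected cross-reference defect with its repair plan.

    OBSOLETE_TARGET: ``targets`` holds the single obsolete term; the repair is
    ``follow-replaced-by:<id>`` or ``drop``.  MULTILEVEL: ``targets`` holds
    the referenced group with the common ancestor first when one exists; the
    repair is ``collapse-to-parent:<id>`` or ``unrepaired``.
    """

    kind: DiscrepancyKind
    source: TermRef
    targets: tuple[TermRef, ...]
    repair: str

    @property
    def repairable(self) -> bool:
        return self.repair != "unrepaired"


@dataclass
class MatchingBuild:
    """Output of :func:`extract_matchings`."""

    clusters: list[DiseaseCluster]
    matchings: list[Matching]

    def __iter__(self):
        # allow ``matchings, clusters = extract_matchings(...)`` unpacking
        return iter((self.matchings, self.clusters))


@dataclass(frozen=True)
class RepairAction:
    discrepancy: Discrepancy
    applied: str


_PROVENANCE_RANK = {"direct": 0, "reverse": 1, "hub-bridged": 2}


def _check_namespaces(
    ontologies: Mapping[str, Ontology],
    preference_order: Sequence[str],
    hub_namespaces: Iterable[str],
    namespaces: Sequence[str],
) -> None:
    known = set(namespaces)
    for ns in preference_order:
        if ns not in known:
            raise ConfigurationError(f"unknown namespace in preference order: {ns!r}")
    for ns in hub_namespaces:
        if ns not in known:
            raise ConfigurationError(f"unknown hub namespace: {ns!r}")
    for ns in ontologies:
        if ns not in known:
            raise ConfigurationError(f"loaded ontology has unconfigured namespace: {ns!r}")


def _require_acyclic(ontologies: Mapping[str, Ontology], force: bool) -> None:
    if force:
        return
    for ns in sorted(ontologies):
        report = validate_ontology(ontologies[ns])
        if report.cycles:
            raise CyclicHierarchyError(
                f"{ns} hierarchy contains {len(report.cycles)} is_a cycle(s); "
                "pass force=True to proceed"
            )


def _resolves_obsolete(ontologies: Mapping[str, Ontology], ref: TermRef) -> bool:
    ontology = ontologies.get(ref.ontology)
    if ontology is None:
        return False
    term = ontology.terms.get(ref.local_id)
    return term is not None and term.obsolete


def extract_matchings(
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
    preference_order: Sequence[str] | None = None,
    hub_namespaces: Iterable[str] = ("UMLS",),
    *,
    namespaces: Sequence[str] = DEFAULT_NAMESPACES,
    evidence: str = "direct+reverse+hub",
    keep_first: bool = False,
    force: bool = False,
) -> MatchingBuild:
    """Build disease clusters and their s=1 matchings from loaded ontologies.

    Every term of the head preference namespace seeds a cluster; members are
    gathered from direct, reverse and hub-bridged evidence (per ``evidence``
    mode).  Terms of other namespaces that end up in no cluster then seed
    their own clusters, walking the preference order — so the preferred
    ontology of a cluster is always the first preference-order namespace it
    contains.  Atomicity is enforced per cluster: when two distinct terms of
    one namespace are proposed, neither is admitted (the conflict is recorded
    for curation) unless ``keep_first`` is set, in which case the candidate
    with the strongest evidence (direct < reverse < hub) and smallest id wins.

    The result is invariant under permutation of the input collection.
    """
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}
    if preference_order is None or not preference_order:
        preference_order = ["MONDO"]
    if evidence not in EVIDENCE_MODES:
        raise ConfigurationError(f"unknown evidence mode {evidence!r}")
    _check_namespaces(ontologies, preference_order, hub_namespaces, namespaces)
    _require_acyclic(ontologies, force)

    hub_set = set(hub_namespaces)
    known = set(namespaces)
    use_reverse = evidence != "direct"
    use_hub = evidence == "direct+reverse+hub"

    # full preference order: configured order first, then remaining
    # namespaces in configured column order
    order = list(preference_order) + [
        ns for ns in namespaces if ns not in preference_order
    ]
    loaded_order = [ns for ns in order if ns in ontologies]

    # reverse index: (target ns, target id) -> [(source ns, source id)]
    reverse_index: dict[TermRef, list[TermRef]] = {}
    for ns in loaded_order:
        for term in ontologies[ns].active_terms():
            for xref in term.xrefs:
                if xref.target_ontology in known:
                    reverse_index.setdefault(xref.target, []).append(term.ref)

    clusters: list[DiseaseCluster] = []
    assigned: set[TermRef] = set()
    preferred_taken: set[TermRef] = set()

    def collect(preferred: TermRef, label: str) -> DiseaseCluster:
        # candidates[ns][local_id] = best provenance tag
        candidates: dict[str, dict[str, str]] = {}

        def propose(ref: TermRef, tag: str) -> None:
            if ref.ontology == preferred.ontology or ref.ontology not in known:
                return
            if ref in preferred_taken:
                return  # a cluster identity elsewhere, never a member here
            if _resolves_obsolete(ontologies, ref):
                return  # obsolete targets are repair material, not members
            slot = candidates.setdefault(ref.ontology, {})
            prev = slot.get(ref.local_id)
            if prev is None or _PROVENANCE_RANK[tag] < _PROVENANCE_RANK[prev]:
                slot[ref.local_id] = tag

        pref_term = ontologies[preferred.ontology].terms[preferred.local_id]
        for xref in sorted(pref_term.xrefs):
            propose(xref.target, "direct")
        if use_reverse:
            for src in sorted(reverse_index.get(preferred, ())):
                propose(src, "reverse")
        if use_hub:
            # one hop through hub members already gathered
            hub_members = [
                TermRef(ns, min(ids, key=lambda i: (_PROVENANCE_RANK[ids[i]], i)))
                if len(ids) > 1 else TermRef(ns, next(iter(ids)))
                for ns, ids in candidates.items()
                if ns in hub_set and len(ids) == 1
            ]
            for hub_ref in hub_members:
                for src in sorted(reverse_index.get(hub_ref, ())):
                    propose(src, "hub-bridged")
                hub_ont = ontologies.get(hub_ref.ontology)
                if hub_ont is not None and hub_ref.local_id in hub_ont.terms:
                    hub_term = hub_ont.terms[hub_ref.local_id]
                    if not hub_term.obsolete:
                        for xref in sorted(hub_term.xrefs):
                            propose(xref.target, "hub-bridged")

        cluster = DiseaseCluster(preferred=preferred, label=label)
        for ns in sorted(candidates):
            ids = candidates[ns]
            if len(ids) == 1:
                (lid, tag), = ids.items()
                cluster.members[ns] = lid
                cluster.provenance[ns] = tag
            elif keep_first:
                lid = min(ids, key=lambda i: (_PROVENANCE_RANK[ids[i]], i))
                cluster.members[ns] = lid
                cluster.provenance[ns] = ids[lid]
                cluster.conflicts[ns] = sorted(ids)
            else:
                cluster.conflicts[ns] = sorted(ids)
        return cluster

    for ns in loaded_order:
        for term in ontologies[ns].active_terms():
            if term.ref in assigned:
                continue
            preferred_taken.add(term.ref)
            cluster = collect(term.ref, term.label)
            clusters.append(cluster)
            assigned.add(term.ref)
            assigned.update(cluster.member_refs())

    clusters.sort(key=lambda c: (c.preferred.ontology, c.preferred.local_id))
    matchings = [m for c in clusters for m in c.matchings()]
    return MatchingBuild(clusters=clusters, matchings=matchings)


# ---------------------------------------------------------------------------
# Discrepancy detection and repair
# ---------------------------------------------------------------------------


def detect_obsolete_refs(
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
) -> list[Discrepancy]:
    """Type-1 discrepancies: xrefs whose target term is obsolete.

    One discrepancy per (source term, obsolete target) pair, in deterministic
    order.  Targets in unloaded ontologies cannot be checked and are skipped.
    """
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}
    found: list[Discrepancy] = []
    for ns in sorted(ontologies):
        for term in ontologies[ns].active_terms():
            for xref in sorted(term.xrefs):
                target_ont = ontologies.get(xref.target_ontology)
                if target_ont is None:
                    continue
                target = target_ont.terms.get(xref.target_id)
                if target is None or not target.obsolete:
                    continue
                replacement = _follow_replaced_by(target_ont, target.local_id)
                repair = (
                    f"follow-replaced-by:{replacement}" if replacement else "drop"
                )
                found.append(
                    Discrepancy(
                        kind=DiscrepancyKind.OBSOLETE_TARGET,
                        source=term.ref,
                        targets=(xref.target,),
                        repair=repair,
                    )
                )
    return found


def _follow_replaced_by(ontology: Ontology, local_id: str) -> str | None:
    """Chase a replaced_by chain to a live term; None if none exists."""
    seen = set()
    current = ontology.terms.get(local_id)
    while current is not None and current.obsolete:
        if current.local_id in seen or not current.replaced_by:
            return None
        seen.add(current.local_id)
        current = ontology.terms.get(current.replaced_by)
    return current.local_id if current is not None else None


def detect_multilevel_refs(
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
) -> list[Discrepancy]:
    """Type-2 discrepancies: a term referencing b together with b's children.

    For each source term and target namespace the referenced group is
    examined: if one referenced target is a strict ancestor of every other,
    the repair collapses the group to that ancestor; a multi-target group
    with no such common referenced ancestor is reported unrepaired.  Only the
    referenced set is considered — inferring an unreferenced common ancestor
    would be close matching, which is out of scope.
    """
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}
    closures: dict[str, dict[str, set[str]]] = {}

    def ancestors_of(ns: str, local_id: str) -> set[str]:
        if ns not in closures:
            g = ontologies[ns].hierarchy()
            closures[ns] = {n: nx.descendants(g, n) for n in g}
        return closures[ns].get(local_id, set())

    found: list[Discrepancy] = []
    for ns in sorted(ontologies):
        for term in ontologies[ns].active_terms():
            by_target_ns: dict[str, list[RawXref]] = {}
            for xref in sorted(term.xrefs):
                if xref.target_ontology in ontologies:
                    by_target_ns.setdefault(xref.target_ontology, []).append(xref)
            for target_ns in sorted(by_target_ns):
                group = by_target_ns[target_ns]
                if len(group) < 2:
                    continue
                ids = [x.target_id for x in group]
                resolvable = all(
                    not _resolves_missing(ontologies[target_ns], i) for i in ids
                )
                root = None
                if resolvable:
                    for candidate in ids:
                        others = [i for i in ids if i != candidate]
                        if others and all(
                            candidate in ancestors_of(target_ns, i) for i in others
                        ):
                            root = candidate
                            break
                targets = tuple(
                    TermRef(target_ns, i)
                    for i in ([root] + sorted(i for i in ids if i != root)
                              if root else sorted(ids))
                )
                repair = f"collapse-to-parent:{root}" if root else "unrepaired"
                found.append(
                    Discrepancy(
                        kind=DiscrepancyKind.MULTILEVEL,
                        source=term.ref,
                        targets=targets,
                        repair=repair,
                    )
                )
    return found


def _resolves_missing(ontology: Ontology, local_id: str) -> bool:
    return local_id not in ontology.terms


def repair_matchings(
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
    discrepancies: Sequence[Discrepancy],
) -> tuple[dict[str, Ontology], list[RepairAction]]:
    """Apply repair plans on a copy of the xref layer; sources stay untouched.

    Obsolete targets are redirected to their replacement (or the xref is
    dropped when none exists); repairable multilevel groups keep only the
    common ancestor.  Unrepaired discrepancies leave xrefs alone and are
    carried into the curation report.  Running detect+repair a second time
    finds only the unrepaired set.
    """
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}
    repaired = {ns: o.copy() for ns, o in ontologies.items()}
    log: list[RepairAction] = []
    for disc in discrepancies:
        term = repaired[disc.source.ontology].terms[disc.source.local_id]
        if not disc.repairable:
            log.append(RepairAction(disc, "left for curation"))
            continue
        if disc.kind is DiscrepancyKind.OBSOLETE_TARGET:
            (target,) = disc.targets
            stale = {x for x in term.xrefs if x.target == target}
            term.xrefs -= stale
            if disc.repair.startswith("follow-replaced-by:"):
                new_id = disc.repair.split(":", 1)[1]
                for x in stale:
                    term.xrefs.add(
                        RawXref(target.ontology, new_id, x.raw_text)
                    )
                applied = f"redirected {target} -> {target.ontology}:{new_id}"
            else:
                applied = f"dropped xref to obsolete {target}"
        else:  # MULTILEVEL, repairable: keep the first target, drop the rest
            keep = disc.targets[0]
            drop = set(disc.targets[1:])
            term.xrefs = {x for x in term.xrefs if x.target not in drop}
            applied = f"collapsed {len(drop)} child reference(s) to {keep}"
        logger.info("repair %s %s: %s", disc.kind.value, disc.source, applied)
        log.append(RepairAction(disc, applied))
    return repaired, log


def detect_and_repair(
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
) -> tuple[dict[str, Ontology], list[Discrepancy], list[RepairAction]]:
    """Convenience pipeline: run both detectors, then repair."""
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}
    discrepancies = detect_obsolete_refs(ontologies) + detect_multilevel_refs(
        ontologies
    )
    repaired, log = repair_matchings(ontologies, discrepancies)
    return repaired, discrepancies, log


# ---------------------------------------------------------------------------
# Atomicity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomicityViolation:
    cluster: TermRef
    namespace: str
    candidates: tuple[str, ...]


def validate_atomicity(clusters: Sequence[DiseaseCluster]) -> list[AtomicityViolation]:
    """Report clusters where >=2 terms of one namespace were proposed.

    Under the default policy such clusters carry no member for the namespace;
    all candidates are listed for curation.
    """
    violations = []
    for cluster in clusters:
        for ns in sorted(cluster.conflicts):
            violations.append(
                AtomicityViolation(
                    cluster=cluster.preferred,
                    namespace=ns,
                    candidates=tuple(cluster.conflicts[ns]),
                )
            )
    return violations


# ---------------------------------------------------------------------------
# Cross-reference flat file
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("preferred_id", "preferred_ontology", "label")


def write_xref_tsv(
    clusters: Sequence[DiseaseCluster],
    stream: TextIO,
    namespaces: Sequence[str] = DEFAULT_NAMESPACES,
) -> int:
    """Write the cross-reference flat file; returns the data-row count.

    One row per cluster, ordered lexicographically by preferred id; one
    column per configured namespace holding the member local id or empty.
    """
    stream.write("\t".join(_FIXED_COLUMNS + tuple(namespaces)) + "\n")
    count = 0
    for cluster in sorted(
        clusters, key=lambda c: (c.preferred.local_id, c.preferred.ontology)
    ):
        cells = [cluster.preferred.local_id, cluster.preferred.ontology, cluster.label]
        cells += [cluster.members.get(ns, "") for ns in namespaces]
        stream.write("\t".join(cells) + "\n")
        count += 1
    return count


def read_xref_tsv(stream: TextIO) -> list[DiseaseCluster]:
    """Read a cross-reference flat file back into clusters.

    Raises on duplicate preferred ids and on multi-value member cells;
    provenance is tagged ``file`` since the flat file does not store it.
    """
    lines = stream.read().splitlines()
    if not lines:
        raise ValueError("cross-reference file is empty (no header)")
    header = lines[0].split("\t")
    if tuple(header[:3]) != _FIXED_COLUMNS:
        raise ValueError(
            f"cross-reference header must start with {_FIXED_COLUMNS}, got {header[:3]}"
        )
    namespaces = header[3:]
    clusters: list[DiseaseCluster] = []
    seen: set[str] = set()
    for rowno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"row {rowno}: expected {len(header)} cells, got {len(cells)}")
        preferred_id, preferred_ns, label = cells[0], cells[1], cells[2]
        if preferred_id in seen:
            raise ValueError(f"row {rowno}: duplicate preferred_id {preferred_id!r}")
        seen.add(preferred_id)
        cluster = DiseaseCluster(
            preferred=TermRef(preferred_ns, preferred_id), label=label
        )
        for ns, cell in zip(namespaces, cells[3:]):
            cell = cell.strip()
            if not cell:
                continue
            if "|" in cell:
                raise ValueError(
                    f"row {rowno}: namespace column {ns} holds multiple values {cell!r}"
                )
            if ns == preferred_ns:
                raise ValueError(
                    f"row {rowno}: member in the preferred namespace column {ns}"
                )
            cluster.members[ns] = cell
            cluster.provenance[ns] = "file"
        clusters.append(cluster)
    return clusters


def write_curation_report(
    discrepancies: Sequence[Discrepancy],
    violations: Sequence[AtomicityViolation],
    stream: TextIO,
) -> int:
    """TSV of discrepancies and atomicity violations for manual curation."""
    stream.write("kind\tsource\ttargets\trepair\n")
    count = 0
    for d in discrepancies:
        targets = "|".join(str(t) for t in d.targets)
        stream.write(f"{d.kind.value}\t{d.source}\t{targets}\t{d.repair}\n")
        count += 1
    for v in violations:
        targets = "|".join(f"{v.namespace}:{c}" for c in v.candidates)
        stream.write(f"ATOMICITY\t{v.cluster}\t{targets}\tunrepaired\n")
        count += 1
    return count


# ---------------------------------------------------------------------------
# Contribution statistics
# ---------------------------------------------------------------------------


def contribution_stats(
    clusters: Sequence[DiseaseCluster],
    namespaces: Sequence[str] = DEFAULT_NAMESPACES,
):
    """Per-ontology contribution table (plus a Total row).

    terms_only
        clusters whose sole content is a preferred term of this namespace
        (no cross-references anywhere).
    preferred_terms
        clusters whose preferred term comes from this namespace (inclusive
        of the terms_only set; the exclusive breakdown is also reported).
    references
        preferred appearances plus cluster memberships of the namespace.
    unique_references
        distinct local ids of the namespace across all clusters.
    """
    import pandas as pd

    rows = []
    for ns in namespaces:
        terms_only = sum(
            1
            for c in clusters
            if c.preferred.ontology == ns and not c.members
        )
        preferred = sum(1 for c in clusters if c.preferred.ontology == ns)
        references = preferred + sum(1 for c in clusters if ns in c.members)
        unique: set[str] = {
            c.preferred.local_id for c in clusters if c.preferred.ontology == ns
        }
        unique.update(c.members[ns] for c in clusters if ns in c.members)
        rows.append(
            {
                "ontology": ns,
                "terms_only": terms_only,
                "preferred_terms": preferred,
                "preferred_terms_excl_only": preferred - terms_only,
                "references": references,
                "unique_references": len(unique),
            }
        )
    frame = pd.DataFrame(rows).set_index("ontology")
    frame.loc["Total"] = frame.sum()
    return frame
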