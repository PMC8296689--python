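"""The merged multi-ontology disease graph and its transitive queries.

Each disease cluster becomes one node carrying the cluster's full attribute
map (one term id per contributing ontology); every is_a assertion of every
source ontology whose two endpoint terms both belong to clusters becomes a
child -> parent edge labelled with its source ontology.  Parallel edges from
different ontologies are kept, never collapsed, so queries can be scoped to
any subset of hierarchies and provenance stays visible.

Transitive subsumption queries (all descendants / ancestors of a term,
across any subset of hierarchies) replace the logical-inference rules a
graph database engine would supply: plain reachability over the labelled
union graph.  A term can be looked up through any of its ontology ids —
querying by a DOID id or an ICD-10 code resolves to the same disease node.

Per-ontology subgraphs are acyclic whenever the source ontology is, but the
cross-ontology union may contain cycles where two ontologies disagree on
direction; those are detected and reported with their edge labels rather
than silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx

from .model import Ontology, TermRef
from .xref import DiseaseCluster

__all__ = [
    "ALL",
    "MergedDiseaseNode",
    "HierarchyEdge",
    "MergedGraph",
    "MergeCycle",
    "CoverageReport",
    "TermLookupError",
    "build_merged_graph",
    "descendants",
    "ancestors",
    "detect_merge_cycles",
    "write_edge_tsv",
    "write_node_tsv",
]

#: Scope sentinel meaning "every source ontology".
ALL = "ALL"


class TermLookupError(KeyError):
    """A query root did not resolve to exactly one disease node."""


@dataclass
class MergedDiseaseNode:
    """One disease with its per-ontology term attributes."""

    cluster: DiseaseCluster
    attributes: dict[str, str]
    node_key: TermRef

    def __hash__(self) -> int:
        return hash(self.node_key)

    def __eq__(self, other) -> bool:
        return isinstance(other, MergedDiseaseNode) and self.node_key == other.node_key

    def __repr__(self) -> str:  # pragma: no cover
        return f"MergedDiseaseNode({self.node_key})"


@dataclass(frozen=True, order=True)
class HierarchyEdge:
    """A child -> parent assertion attributed to one source ontology."""

    child: TermRef
    parent: TermRef
    source_ontology: str


@dataclass(frozen=True)
class MergeCycle:
    """An elementary cycle of the union graph with per-step edge labels."""

    nodes: tuple[TermRef, ...]
    labels: tuple[frozenset[str], ...]

    @property
    def ontologies(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.labels:
            out |= step
        return frozenset(out)


@dataclass
class CoverageReport:
    """Terms per ontology that were / were not representable in the graph."""

    covered: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)


@dataclass
class MergedGraph:
    nodes: dict[TermRef, MergedDiseaseNode]
    edges: set[HierarchyEdge]
    graph: nx.MultiDiGraph                       # child -> parent, key = ontology
    attribute_index: dict[TermRef, tuple[TermRef, ...]]
    coverage: CoverageReport
    cycle_report: list[MergeCycle] = field(default_factory=list)

    def ontology_labels(self) -> set[str]:
        return {e.source_ontology for e in self.edges}

    def resolve(self, root: TermRef | str) -> MergedDiseaseNode:
        """Resolve a query root given in any namespace to its disease node.

        Accepts a :class:`TermRef` or a bare local id (searched across all
        namespaces).  Ambiguity — an id attributed to several nodes — is an
        error listing the candidates.
        """
        if isinstance(root, str):
            hits = sorted(
                {k for ref, keys in self.attribute_index.items()
                 if ref.local_id == root for k in keys}
            )
        else:
            if root in self.nodes:
                return self.nodes[root]
            hits = sorted(self.attribute_index.get(root, ()))
        if not hits:
            raise TermLookupError(f"no disease node carries term {root}")
        if len(hits) > 1:
            raise TermLookupError(
                f"term {root} is ambiguous across nodes: "
                + ", ".join(str(h) for h in hits)
            )
        return self.nodes[hits[0]]


def build_merged_graph(
    clusters: Sequence[DiseaseCluster],
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
) -> MergedGraph:
    """Merge every ontology's is_a hierarchy over the disease clusters.

    An edge (child node, parent node, ontology O) exists iff O asserts is_a
    between the two nodes' O-attribute terms.  Terms of O attributed to no
    cluster are skipped and tallied in the coverage report.  Self-loops
    (both terms attributed to the same node) are never emitted.
    """
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}

    nodes: dict[TermRef, MergedDiseaseNode] = {}
    attr_index: dict[TermRef, set[TermRef]] = {}
    for cluster in clusters:
        key = cluster.preferred
        if key in nodes:
            raise ValueError(f"duplicate cluster preferred term {key}")
        nodes[key] = MergedDiseaseNode(
            cluster=cluster, attributes=cluster.attributes(), node_key=key
        )
        for ns, lid in nodes[key].attributes.items():
            attr_index.setdefault(TermRef(ns, lid), set()).add(key)

    g = nx.MultiDiGraph()
    g.add_nodes_from(nodes)
    edges: set[HierarchyEdge] = set()
    coverage = CoverageReport()
    for ns in sorted(ontologies):
        ontology = ontologies[ns]
        covered = skipped = 0
        for term in ontology.active_terms():
            child_keys = attr_index.get(TermRef(ns, term.local_id))
            if not child_keys:
                skipped += 1
                continue
            covered += 1
            for parent_id in sorted(term.parents):
                parent = ontology.terms.get(parent_id)
                if parent is None or parent.obsolete:
                    continue
                parent_keys = attr_index.get(TermRef(ns, parent_id))
                if not parent_keys:
                    continue
                for ck in sorted(child_keys):
                    for pk in sorted(parent_keys):
                        if ck == pk:
                            continue
                        edge = HierarchyEdge(ck, pk, ns)
                        if edge not in edges:
                            edges.add(edge)
                            g.add_edge(ck, pk, key=ns)
        coverage.covered[ns] = covered
        coverage.skipped[ns] = skipped

    merged = MergedGraph(
        nodes=nodes,
        edges=edges,
        graph=g,
        attribute_index={k: tuple(sorted(v)) for k, v in attr_index.items()},
        coverage=coverage,
    )
    merged.cycle_report = detect_merge_cycles(merged)
    return merged


def _scope_set(graph: MergedGraph, scope) -> set[str]:
    if scope == ALL or scope is None:
        return graph.ontology_labels()
    scope = set([scope] if isinstance(scope, str) else scope)
    if not scope:
        raise ValueError("scope must be non-empty or ALL")
    return scope


def _reachable(
    graph: MergedGraph, start: TermRef, scope: set[str], downward: bool
) -> set[TermRef]:
    """Visited-set reachability; terminates on cyclic unions."""
    g = graph.graph
    seen: set[TermRef] = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        if downward:
            steps = (
                (u, ks) for u, _, ks in g.in_edges(node, keys=True)
            )
        else:
            steps = (
                (v, ks) for _, v, ks in g.out_edges(node, keys=True)
            )
        for nbr, key in steps:
            if key in scope and nbr not in seen and nbr != start:
                seen.add(nbr)
                frontier.append(nbr)
    return seen


def descendants(
    graph: MergedGraph,
    root: TermRef | str,
    scope=ALL,
    *,
    include_self: bool = False,
) -> set[MergedDiseaseNode]:
    """All sub-classes of ``root`` across the in-scope hierarchies.

    Follows child -> parent edges in reverse, restricted to edges whose
    source ontology is in ``scope``.  Non-reflexive by default; pass
    ``include_self=True`` to include the root node itself.
    """
    node = graph.resolve(root)
    keys = _reachable(graph, node.node_key, _scope_set(graph, scope), downward=True)
    result = {graph.nodes[k] for k in keys}
    if include_self:
        result.add(node)
    return result


def ancestors(
    graph: MergedGraph,
    root: TermRef | str,
    scope=ALL,
    *,
    include_self: bool = False,
) -> set[MergedDiseaseNode]:
    """All super-classes of ``root`` across the in-scope hierarchies."""
    node = graph.resolve(root)
    keys = _reachable(graph, node.node_key, _scope_set(graph, scope), downward=False)
    result = {graph.nodes[k] for k in keys}
    if include_self:
        result.add(node)
    return result


def detect_merge_cycles(graph: MergedGraph, limit: int = 1000) -> list[MergeCycle]:
    """Elementary cycles of the union graph, with edge labels per step.

    Enumeration is capped at ``limit`` cycles; the labels show which
    ontologies disagree so curators can localise the conflict.
    """
    cycles: list[MergeCycle] = []
    seen: set[tuple[TermRef, ...]] = set()
    for cycle in nx.simple_cycles(graph.graph):
        # rotate so the smallest node leads: deterministic across runs, and
        # parallel-edge variants of one node cycle collapse to one report
        pivot = cycle.index(min(cycle))
        nodes = tuple(cycle[pivot:] + cycle[:pivot])
        if nodes in seen:
            continue
        seen.add(nodes)
        labels = []
        for i, u in enumerate(nodes):
            v = nodes[(i + 1) % len(nodes)]
            labels.append(frozenset(graph.graph[u][v]))
        cycles.append(MergeCycle(nodes=nodes, labels=tuple(labels)))
        if len(cycles) >= limit:
            break
    cycles.sort(key=lambda c: c.nodes)
    return cycles


def write_edge_tsv(graph: MergedGraph, stream: TextIO) -> int:
    """Deterministic edge-list export (child, parent, source ontology)."""
    stream.write("child_ontology\tchild_id\tparent_ontology\tparent_id\tsource_ontology\n")
    count = 0
    for e in sorted(graph.edges):
        stream.write(
            f"{e.child.ontology}\t{e.child.local_id}\t"
            f"{e.parent.ontology}\t{e.parent.local_id}\t{e.source_ontology}\n"
        )
        count += 1
    return count


def write_node_tsv(
    graph: MergedGraph, stream: TextIO, namespaces: Sequence[str] | None = None
) -> int:
    """Node table mirroring the cross-reference flat file."""
    from .model import DEFAULT_NAMESPACES
    from .xref import write_xref_tsv

    clusters = [n.cluster for n in graph.nodes.values()]
    return write_xref_tsv(clusters, stream, namespaces or DEFAULT_NAMESPACES)
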