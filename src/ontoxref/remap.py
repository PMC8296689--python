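"""Remapping one ontology's terms onto another ontology's hierarchy.

Every disease node carrying a source-namespace term is remapped to the
target namespace: MAPPED when the same node also carries a target term
(exact cluster co-membership); otherwise PLACED_BY_ANCESTOR with the nearest
merged-graph ancestors that do carry target terms; otherwise UNMAPPED.
Ancestor placement walks all hierarchies (scope = ALL), so a MeSH term with
no MONDO equivalent can still be positioned inside the MONDO tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import TextIO

from .model import TermRef
from .graph import ALL, MergedGraph, ancestors
from .xref import ConfigurationError

__all__ = [
    "RemapStatus",
    "RemapResult",
    "remap_terms",
    "hierarchy_view",
    "coverage_report",
    "write_remap_tsv",
]


class RemapStatus(str, Enum):
    MAPPED = "MAPPED"
    PLACED_BY_ANCESTOR = "PLACED_BY_ANCESTOR"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class RemapResult:
    """Outcome of remapping one source term into the target namespace."""

    source_term: TermRef
    status: RemapStatus
    target_term: TermRef | None = None
    placement: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status is RemapStatus.MAPPED and self.target_term is None:
            raise ValueError("MAPPED result requires a target term")
        if self.status is RemapStatus.UNMAPPED and (
            self.target_term is not None or self.placement
        ):
            raise ValueError("UNMAPPED result carries no target or placement")


def _check_ns(graph: MergedGraph, ns: str) -> None:
    known = {ref.ontology for ref in graph.attribute_index}
    known.update(graph.ontology_labels())
    if ns not in known:
        raise ConfigurationError(f"namespace {ns!r} is not present in the graph")


def remap_terms(
    graph: MergedGraph, source_ns: str, target_ns: str
) -> list[RemapResult]:
    """Remap every source-namespace term onto the target namespace.

    Results are ordered by source id.  "Nearest" ancestors are the minimal
    antichain of ancestors carrying a target term: an ancestor is dropped
    when another qualifying ancestor lies strictly between it and the source
    node.  Incomparable ties are all kept, sorted.
    """
    _check_ns(graph, source_ns)
    _check_ns(graph, target_ns)
    results: list[RemapResult] = []
    for key in sorted(graph.nodes):
        node = graph.nodes[key]
        source_id = node.attributes.get(source_ns)
        if source_id is None:
            continue
        source_term = TermRef(source_ns, source_id)
        target_id = node.attributes.get(target_ns)
        if target_id is not None:
            results.append(
                RemapResult(
                    source_term=source_term,
                    status=RemapStatus.MAPPED,
                    target_term=TermRef(target_ns, target_id),
                )
            )
            continue
        anc = {
            a
            for a in ancestors(graph, key, scope=ALL)
            if target_ns in a.attributes
        }
        # minimal antichain: drop any ancestor that is an ancestor of
        # another candidate (i.e. strictly further from the source node)
        minimal = {
            a
            for a in anc
            if not any(
                a in ancestors(graph, b.node_key, scope=ALL)
                for b in anc
                if b is not a
            )
        }
        if minimal:
            placement = tuple(sorted(a.attributes[target_ns] for a in minimal))
            results.append(
                RemapResult(
                    source_term=source_term,
                    status=RemapStatus.PLACED_BY_ANCESTOR,
                    placement=placement,
                )
            )
        else:
            results.append(
                RemapResult(source_term=source_term, status=RemapStatus.UNMAPPED)
            )
    results.sort(key=lambda r: r.source_term)
    return results


def hierarchy_view(graph: MergedGraph, viewpoint_ns: str) -> MergedGraph:
    """The merged graph as seen through one ontology's hierarchy.

    Restricts to nodes carrying a viewpoint term and to edges asserted by
    the viewpoint ontology — exactly that ontology's own subtree projected
    onto clusters.
    """
    from .graph import CoverageReport, MergedGraph as MG
    import networkx as nx

    _check_ns(graph, viewpoint_ns)
    keep_nodes = {
        k: n for k, n in graph.nodes.items() if viewpoint_ns in n.attributes
    }
    keep_edges = {
        e
        for e in graph.edges
        if e.source_ontology == viewpoint_ns
        and e.child in keep_nodes
        and e.parent in keep_nodes
    }
    g = nx.MultiDiGraph()
    g.add_nodes_from(keep_nodes)
    for e in sorted(keep_edges):
        g.add_edge(e.child, e.parent, key=e.source_ontology)
    attr_index = {
        ref: tuple(k for k in keys if k in keep_nodes)
        for ref, keys in graph.attribute_index.items()
        if any(k in keep_nodes for k in keys)
    }
    view = MG(
        nodes=keep_nodes,
        edges=keep_edges,
        graph=g,
        attribute_index=attr_index,
        coverage=CoverageReport(),
    )
    return view


def coverage_report(
    graph: MergedGraph, source_ns: str, target_ns: str
) -> dict[str, int]:
    """Counts of MAPPED / PLACED_BY_ANCESTOR / UNMAPPED remap outcomes.

    The counts sum to the number of disease nodes carrying a source term.
    """
    tally = Counter(r.status.value for r in remap_terms(graph, source_ns, target_ns))
    return {status.value: tally.get(status.value, 0) for status in RemapStatus}


def write_remap_tsv(results, stream: TextIO) -> int:
    """TSV export: source_id, status, target_id, placement (pipe-separated)."""
    stream.write("source_id\tstatus\ttarget_id\tplacement\n")
    count = 0
    for r in results:
        target = r.target_term.local_id if r.target_term else ""
        stream.write(
            f"{r.source_term.local_id}\t{r.status.value}\t{target}\t"
            f"{'|'.join(r.placement)}\n"
        )
        count += 1
    return count
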