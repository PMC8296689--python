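"""End-to-end convenience pipeline: load, repair, cluster, merge.

Thin orchestration over the library modules so the CLI, tests and scripts
run the identical sequence: parse ontology files, detect and repair
cross-reference discrepancies, extract atomic clusters, then build the
merged multi-ontology graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .config import Config, canonical_namespace
from .graph import MergedGraph, build_merged_graph
from .model import Ontology, parse_hierarchy_tsv, parse_obo_subset
from .xref import (
    AtomicityViolation,
    Discrepancy,
    DiseaseCluster,
    Matching,
    RepairAction,
    detect_multilevel_refs,
    detect_obsolete_refs,
    extract_matchings,
    repair_matchings,
    validate_atomicity,
)

__all__ = ["PipelineResult", "load_ontology_file", "load_ontology_dir", "run_pipeline"]


@dataclass
class PipelineResult:
    ontologies: dict[str, Ontology]          # repaired xref layer
    discrepancies: list[Discrepancy]
    repair_log: list[RepairAction]
    clusters: list[DiseaseCluster]
    matchings: list[Matching]
    violations: list[AtomicityViolation]
    graph: MergedGraph


def load_ontology_file(path: str | Path, namespace: str | None = None) -> Ontology:
    """Load one ontology file; dialect by extension (.obo / .tsv).

    The namespace defaults to the canonicalised file stem (``MONDO.tsv`` ->
    MONDO, ``doid.obo`` -> DOID).
    """
    path = Path(path)
    ns = namespace or canonical_namespace(path.stem)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".obo":
            return parse_obo_subset(fh, ns)
        return parse_hierarchy_tsv(fh, ns)


def load_ontology_dir(directory: str | Path) -> dict[str, Ontology]:
    """Load every .obo / .tsv ontology file of a directory."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".obo", ".tsv")
    )
    if not paths:
        raise FileNotFoundError(f"no ontology files (.obo/.tsv) in {directory}")
    ontologies: dict[str, Ontology] = {}
    for path in paths:
        ontology = load_ontology_file(path)
        if ontology.namespace in ontologies:
            raise ValueError(f"namespace {ontology.namespace} loaded twice")
        ontologies[ontology.namespace] = ontology
    return ontologies


def run_pipeline(
    ontologies: Mapping[str, Ontology] | Iterable[Ontology],
    config: Config | None = None,
) -> PipelineResult:
    """Repair discrepancies, extract atomic clusters, build the merged graph."""
    config = config or Config()
    if not isinstance(ontologies, Mapping):
        ontologies = {o.namespace: o for o in ontologies}
    discrepancies = detect_obsolete_refs(ontologies) + detect_multilevel_refs(
        ontologies
    )
    repaired, log = repair_matchings(ontologies, discrepancies)
    build = extract_matchings(
        repaired,
        preference_order=config.preference_order,
        hub_namespaces=config.hub_namespaces,
        namespaces=config.namespaces,
        evidence=config.evidence,
        keep_first=config.keep_first,
        force=config.force,
    )
    violations = validate_atomicity(build.clusters)
    graph = build_merged_graph(build.clusters, repaired)
    return PipelineResult(
        ontologies=repaired,
        discrepancies=discrepancies,
        repair_log=log,
        clusters=build.clusters,
        matchings=build.matchings,
        violations=violations,
        graph=graph,
    )
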