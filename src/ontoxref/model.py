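"""Domain model for source disease ontologies.

An :class:`Ontology` is a flat map of :class:`OntologyTerm` objects carrying
the is_a hierarchy, cross-references (xrefs) into other ontologies, and
obsolescence metadata.  Two on-disk dialects are supported: a restricted OBO
flat-file subset (``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
``xref``, ``is_obsolete`` and ``replaced_by`` tags) and a tab-separated
hierarchy table with pipe-separated multi-value cells.  Both parse to
structurally identical :class:`Ontology` values.

Xref prefixes are normalised against a canonical namespace table so that the
spelling variants found in the wild (``MeSH``/``MSH``/``MESH``,
``ICD-10``/``ICD10CM``, ``ORPHA``/``ORDO`` ...) all match deterministically;
the raw source string is always retained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

import networkx as nx

__all__ = [
    "DEFAULT_NAMESPACES",
    "UNKNOWN_NAMESPACE",
    "TermRef",
    "RawXref",
    "OntologyTerm",
    "Ontology",
    "OntologyParseError",
    "ValidationReport",
    "normalize_xref",
    "canonical_local_id",
    "parse_obo_subset",
    "parse_hierarchy_tsv",
    "write_hierarchy_tsv",
    "validate_ontology",
]

#: Canonical namespace labels, in cross-reference file column order.
DEFAULT_NAMESPACES: tuple[str, ...] = (
    "MONDO", "MESH", "UMLS", "EFO", "NCIT",
    "OMIM", "DOID", "ORPHANET", "HP", "ICD10",
)

UNKNOWN_NAMESPACE = "UNKNOWN"

#: Source prefix spelling -> canonical namespace.
PREFIX_ALIASES: dict[str, str] = {
    "MSH": "MESH", "MESH": "MESH", "MeSH": "MESH",
    "UMLS": "UMLS", "UMLS_CUI": "UMLS", "UMLS CUI": "UMLS",
    "ICD10": "ICD10", "ICD-10": "ICD10", "ICD10CM": "ICD10",
    "OMIM": "OMIM", "MIM": "OMIM",
    "ORPHA": "ORPHANET", "Orphanet": "ORPHANET", "ORPHANET": "ORPHANET",
    "ORDO": "ORPHANET",
    "MONDO": "MONDO", "EFO": "EFO", "NCIT": "NCIT", "NCIt": "NCIT",
    "DOID": "DOID", "HP": "HP", "HPO": "HP",
}

#: Namespaces whose canonical local id is the OBO-style ``PREFIX_localpart``.
#: MeSH/UMLS/OMIM/ICD-10 keep their native codes (D007676, C0022661, 600001,
#: N18.9).
OBO_STYLE: frozenset[str] = frozenset(
    {"MONDO", "EFO", "NCIT", "DOID", "ORPHANET", "HP"}
)


class OntologyParseError(ValueError):
    """Raised for malformed ontology input (with location information)."""


@dataclass(frozen=True, order=True)
class TermRef:
    """A term identified across ontologies: namespace plus local id."""

    ontology: str
    local_id: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.ontology}:{self.local_id}"


@dataclass(frozen=True, order=True)
class RawXref:
    """One cross-reference as found in a source ontology.

    ``raw_text`` preserves the untouched source string so normalisation is
    lossless; ``target_ontology`` is a canonical namespace or ``UNKNOWN``.
    """

    target_ontology: str
    target_id: str
    raw_text: str

    @property
    def target(self) -> TermRef:
        return TermRef(self.target_ontology, self.target_id)


def canonical_local_id(namespace: str, local: str) -> str:
    """Canonical local id for a namespace.

    OBO-style namespaces carry their prefix in the id (``DOID:784`` ->
    ``DOID_784``, ``NCIT:C80078`` -> ``NCIT_C80078``); code-based namespaces
    keep the native code unchanged.
    """
    local = local.strip().replace(":", "_")
    if namespace in OBO_STYLE and not local.upper().startswith(namespace + "_"):
        return f"{namespace}_{local}"
    return local


def normalize_xref(raw: str) -> RawXref:
    """Normalise an xref string like ``MeSH:D007676`` to canonical form.

    Unknown prefixes map to the ``UNKNOWN`` namespace; the raw text is kept
    verbatim in every case.
    """
    text = raw.strip()
    prefix, sep, local = text.partition(":")
    if not sep or not local.strip():
        return RawXref(UNKNOWN_NAMESPACE, text, raw)
    ns = PREFIX_ALIASES.get(prefix.strip())
    if ns is None:
        return RawXref(UNKNOWN_NAMESPACE, text, raw)
    return RawXref(ns, canonical_local_id(ns, local), raw)


@dataclass
class OntologyTerm:
    """One term of one source ontology."""

    ontology: str
    local_id: str
    label: str = ""
    parents: set[str] = field(default_factory=set)
    xrefs: set[RawXref] = field(default_factory=set)
    obsolete: bool = False
    replaced_by: str | None = None

    @property
    def ref(self) -> TermRef:
        return TermRef(self.ontology, self.local_id)

    def copy(self) -> "OntologyTerm":
        return replace(self, parents=set(self.parents), xrefs=set(self.xrefs))


@dataclass
class Ontology:
    """A namespace plus its terms, keyed by local id."""

    namespace: str
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    version_tag: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, local_id: str) -> bool:
        return local_id in self.terms

    def add(self, term: OntologyTerm) -> None:
        if term.local_id in self.terms:
            raise OntologyParseError(
                f"{self.namespace}: duplicate term id {term.local_id!r}"
            )
        self.terms[term.local_id] = term

    def active_terms(self) -> Iterable[OntologyTerm]:
        """Non-obsolete terms in deterministic (lexicographic id) order."""
        for local_id in sorted(self.terms):
            term = self.terms[local_id]
            if not term.obsolete:
                yield term

    def hierarchy(self) -> nx.DiGraph:
        """child -> parent is_a digraph over non-obsolete, resolvable terms.

        Obsolete terms and dangling parent ids are excluded: obsolete terms
        exist only as repair targets and take no part in reasoning.
        """
        g = nx.DiGraph()
        for term in self.active_terms():
            g.add_node(term.local_id)
        for term in self.active_terms():
            for parent in term.parents:
                p = self.terms.get(parent)
                if p is not None and not p.obsolete:
                    g.add_edge(term.local_id, parent)
        return g

    def copy(self) -> "Ontology":
        return Ontology(
            namespace=self.namespace,
            terms={k: t.copy() for k, t in self.terms.items()},
            version_tag=self.version_tag,
        )


# ---------------------------------------------------------------------------
# OBO flat-file subset
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes"}


def _strip_obo_value(value: str) -> str:
    # drop trailing OBO comment ("! chronic kidney disease") and quotes
    bang = value.find(" !")
    if bang != -1:
        value = value[:bang]
    return value.strip().strip('"')


def parse_obo_subset(stream: TextIO | str, namespace: str) -> Ontology:
    """Parse the supported OBO subset into an :class:`Ontology`.

    Only ``[Term]`` stanzas are interpreted; within them the tags ``id``,
    ``name``, ``is_a``, ``xref``, ``is_obsolete`` and ``replaced_by`` are
    recognised and every other tag is ignored.  is_a targets are recorded
    verbatim, so dangling parents are allowed at parse time and surface in
    :func:`validate_ontology`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ontology = Ontology(namespace=namespace)
    stanza: dict | None = None
    stanza_line = 0
    in_term = False
    first_seen: dict[str, int] = {}

    def flush() -> None:
        nonlocal stanza
        if stanza is None:
            return
        if stanza.get("id") is None:
            raise OntologyParseError(
                f"{namespace}: [Term] stanza at line {stanza_line} has no id tag"
            )
        local_id = stanza["id"]
        if local_id in ontology.terms:
            raise OntologyParseError(
                f"{namespace}: duplicate term id {local_id!r} "
                f"(stanzas at lines {first_seen[local_id]} and {stanza_line})"
            )
        first_seen[local_id] = stanza_line
        ontology.add(
            OntologyTerm(
                ontology=namespace,
                local_id=local_id,
                label=stanza.get("name", ""),
                parents=stanza.get("is_a", set()),
                xrefs=stanza.get("xref", set()),
                obsolete=stanza.get("is_obsolete", False),
                replaced_by=stanza.get("replaced_by"),
            )
        )
        stanza = None

    for lineno, raw_line in enumerate(stream, start=1):
        line = raw_line.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                stanza = {"is_a": set(), "xref": set()}
                stanza_line = lineno
            continue
        if not in_term or stanza is None:
            continue
        tag, sep, value = line.partition(":")
        if not sep:
            continue
        tag = tag.strip()
        value = _strip_obo_value(value)
        if tag == "id":
            stanza["id"] = canonical_local_id(namespace, value)
        elif tag == "name":
            stanza["name"] = value
        elif tag == "is_a":
            stanza["is_a"].add(canonical_local_id(namespace, value))
        elif tag == "xref":
            stanza["xref"].add(normalize_xref(value))
        elif tag == "is_obsolete":
            stanza["is_obsolete"] = value.lower() in _TRUTHY
        elif tag == "replaced_by":
            stanza["replaced_by"] = canonical_local_id(namespace, value)
    flush()
    return ontology


# ---------------------------------------------------------------------------
# Hierarchy TSV dialect
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("id", "label", "parents", "xrefs", "obsolete", "replaced_by")
_MANDATORY_COLUMNS = ("id", "label", "parents", "xrefs", "obsolete")


def parse_hierarchy_tsv(stream: TextIO | str, namespace: str) -> Ontology:
    """Parse the hierarchy TSV dialect into an :class:`Ontology`.

    The header row must name ``id``, ``label``, ``parents``, ``xrefs`` and
    ``obsolete`` (``replaced_by`` is optional); ``parents`` and ``xrefs`` are
    pipe-separated lists and ``obsolete`` is literal true/false.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if not lines:
        return Ontology(namespace=namespace)
    header = lines[0].rstrip("\n").split("\t")
    for col in _MANDATORY_COLUMNS:
        if col not in header:
            raise OntologyParseError(
                f"{namespace}: hierarchy TSV is missing mandatory column {col!r}"
            )
    idx = {col: header.index(col) for col in header}
    ontology = Ontology(namespace=namespace)
    for rowno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise OntologyParseError(
                f"{namespace}: row {rowno} has {len(cells)} cells, "
                f"expected {len(header)}"
            )
        get = lambda col: cells[idx[col]].strip() if col in idx else ""
        local_id = canonical_local_id(namespace, get("id"))
        if not local_id:
            raise OntologyParseError(f"{namespace}: row {rowno} has an empty id")
        parents = {
            canonical_local_id(namespace, p)
            for p in get("parents").split("|")
            if p.strip()
        }
        xrefs = {normalize_xref(x) for x in get("xrefs").split("|") if x.strip()}
        replaced = get("replaced_by") or None
        if replaced:
            replaced = canonical_local_id(namespace, replaced)
        ontology.add(
            OntologyTerm(
                ontology=namespace,
                local_id=local_id,
                label=get("label"),
                parents=parents,
                xrefs=xrefs,
                obsolete=get("obsolete").lower() in _TRUTHY,
                replaced_by=replaced,
            )
        )
    return ontology


def write_hierarchy_tsv(ontology: Ontology, stream: TextIO) -> int:
    """Serialise to the hierarchy TSV dialect; returns the data-row count.

    Rows are ordered lexicographically by local id so output is deterministic
    and ``parse_hierarchy_tsv(write_hierarchy_tsv(O)) == O``.
    """
    stream.write("\t".join(TSV_COLUMNS) + "\n")
    count = 0
    for local_id in sorted(ontology.terms):
        term = ontology.terms[local_id]
        xrefs = "|".join(x.raw_text.strip() for x in sorted(term.xrefs))
        row = (
            term.local_id,
            term.label,
            "|".join(sorted(term.parents)),
            xrefs,
            "true" if term.obsolete else "false",
            term.replaced_by or "",
        )
        stream.write("\t".join(row) + "\n")
        count += 1
    return count


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Structural defects of one ontology.  Empty report == clean ontology."""

    namespace: str
    cycles: list[list[str]] = field(default_factory=list)
    dangling_parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete_without_replacement: list[str] = field(default_factory=list)
    active_with_replacement: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.cycles
            or self.dangling_parents
            or self.obsolete_without_replacement
            or self.active_with_replacement
        )

    def summary_lines(self) -> list[str]:
        lines = []
        for cycle in self.cycles:
            lines.append(f"cycle\t{'->'.join(cycle)}")
        for child, parent in self.dangling_parents:
            lines.append(f"dangling_parent\t{child}\t{parent}")
        for t in self.obsolete_without_replacement:
            lines.append(f"obsolete_without_replacement\t{t}")
        for t in self.active_with_replacement:
            lines.append(f"active_with_replacement\t{t}")
        return lines


def validate_ontology(ontology: Ontology) -> ValidationReport:
    """Report is_a cycles, dangling parents and replaced_by inconsistencies.

    Validation never raises; downstream builders decide whether a defect is
    fatal.  Cycle detection runs on non-obsolete terms only.
    """
    report = ValidationReport(namespace=ontology.namespace)
    g = nx.DiGraph()
    for local_id in sorted(ontology.terms):
        term = ontology.terms[local_id]
        for parent in sorted(term.parents):
            if parent not in ontology.terms:
                report.dangling_parents.append((local_id, parent))
        if term.obsolete and not term.replaced_by:
            report.obsolete_without_replacement.append(local_id)
        if not term.obsolete and term.replaced_by:
            report.active_with_replacement.append(local_id)
        if not term.obsolete:
            g.add_node(local_id)
            for parent in term.parents:
                p = ontology.terms.get(parent)
                if p is not None and not p.obsolete:
                    g.add_edge(local_id, parent)
    report.cycles = sorted(sorted(c) for c in nx.simple_cycles(g))
    return report
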