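"""Pipeline configuration: namespaces, preference order, evidence policy."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model import DEFAULT_NAMESPACES, PREFIX_ALIASES
from .xref import EVIDENCE_MODES, ConfigurationError

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    """All knobs of the cross-referencing pipeline.

    ``namespaces`` fixes the cross-reference file column order;
    ``preference_order`` decides which term represents a cluster (head
    first, then fallbacks); ``hub_namespaces`` are bridged through with
    exactly one hop; ``evidence`` selects which evidence sources are used.
    """

    namespaces: list[str] = field(default_factory=lambda: list(DEFAULT_NAMESPACES))
    preference_order: list[str] = field(default_factory=lambda: ["MONDO"])
    hub_namespaces: list[str] = field(default_factory=lambda: ["UMLS"])
    evidence: str = "direct+reverse+hub"
    keep_first: bool = False
    force: bool = False

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_MODES:
            raise ConfigurationError(
                f"evidence must be one of {EVIDENCE_MODES}, got {self.evidence!r}"
            )
        known = set(self.namespaces)
        for ns in list(self.preference_order) + list(self.hub_namespaces):
            if ns not in known:
                raise ConfigurationError(f"namespace {ns!r} is not configured")

    def with_overrides(self, **kwargs) -> "Config":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config file; missing path means all defaults."""
    if path is None:
        return Config()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(data) - {
        "namespaces", "preference_order", "hub_namespaces",
        "evidence", "keep_first", "force",
    }
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)


def canonical_namespace(label: str) -> str:
    """Resolve a namespace spelling (e.g. a file stem) to canonical form."""
    hit = PREFIX_ALIASES.get(label) or PREFIX_ALIASES.get(label.upper())
    if hit is None:
        raise ConfigurationError(f"unrecognised ontology namespace {label!r}")
    return hit
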