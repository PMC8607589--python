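"""Run configuration: prefixes, namespaces and flags, from a TOML file.

A config file is optional everywhere; the defaults reproduce the
standard vocabulary.  Recognized keys::

    base_namespace = "https://example.org/glycopath/"
    sugar_nucleotide_class_iri = "http://purl.obolibrary.org/obo/CHEBI_25609"
    multivalue_separator = "|"
    strict_wurcs = false
    emit_pathway_component = false
    literal_properties = ["bp:id"]

    [prefixes]           # extra prefix -> namespace bindings
    ex = "https://example.org/other#"

    [class_iris]         # per-class IRI overrides
    SugarNucleotide = "http://purl.obolibrary.org/obo/CHEBI_25609"
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .model_builder import (
    DEFAULT_BASE_NAMESPACE,
    DEFAULT_SUGAR_NUCLEOTIDE_IRI,
    VocabularyMap,
)
from .tables_io import DEFAULT_LITERAL_PROPERTIES, DEFAULT_SEPARATOR

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    base_namespace: str = DEFAULT_BASE_NAMESPACE
    sugar_nucleotide_class_iri: str = DEFAULT_SUGAR_NUCLEOTIDE_IRI
    multivalue_separator: str = DEFAULT_SEPARATOR
    strict_wurcs: bool = False
    emit_pathway_component: bool = False
    literal_properties: frozenset[str] = DEFAULT_LITERAL_PROPERTIES
    extra_prefixes: dict[str, str] = field(default_factory=dict)
    class_iri_overrides: dict[str, str] = field(default_factory=dict)

    def vocabulary(self) -> VocabularyMap:
        vocab = VocabularyMap.default(
            base_namespace=self.base_namespace,
            sugar_nucleotide_class_iri=self.sugar_nucleotide_class_iri,
        )
        for prefix, ns in self.extra_prefixes.items():
            vocab.prefix_to_namespace.setdefault(prefix, ns)
        vocab.class_iris.update(self.class_iri_overrides)
        vocab.validate()
        return vocab


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML run configuration; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"config file {path} does not parse: {exc}") from exc
    known = {
        "base_namespace",
        "sugar_nucleotide_class_iri",
        "multivalue_separator",
        "strict_wurcs",
        "emit_pathway_component",
        "literal_properties",
        "prefixes",
        "class_iris",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        base_namespace=data.get("base_namespace", DEFAULT_BASE_NAMESPACE),
        sugar_nucleotide_class_iri=data.get(
            "sugar_nucleotide_class_iri", DEFAULT_SUGAR_NUCLEOTIDE_IRI
        ),
        multivalue_separator=data.get("multivalue_separator", DEFAULT_SEPARATOR),
        strict_wurcs=bool(data.get("strict_wurcs", False)),
        emit_pathway_component=bool(data.get("emit_pathway_component", False)),
        literal_properties=frozenset(
            data.get("literal_properties", DEFAULT_LITERAL_PROPERTIES)
        ),
        extra_prefixes=dict(data.get("prefixes", {})),
        class_iri_overrides=dict(data.get("class_iris", {})),
    )
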