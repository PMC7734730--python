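"""Assembly of the final ontology-linked RDF graph.

Extraction produces triples over literal phrases.  Enrichment mints one
deterministic local URI per distinct normalized phrase (so reused phrases
become shared nodes and the graph connects), attaches the original phrase
to each minted URI with ``rdfs:label``, and binds ontology links with
``owl:sameAs``.  The graph serializes to standard Turtle (via rdflib) and
to the DOT graph language for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import rdflib
from rdflib import Literal as RdfLiteral, URIRef
from rdflib.namespace import OWL, RDFS

from .errors import InvalidInputError, InvalidPhraseError
from .extract import Term, Triple, slug
from .linking import OntologyLink

#: Default namespace IRIs.  The local/role IRIs are package conventions,
#: configurable per run; ``vn.role`` is an accepted alias of ``role``.
DEFAULT_NAMESPACES = {
    "local": "http://example.org/kg/local#",
    "role": "http://example.org/kg/role#",
    "rdfs": str(RDFS),
    "owl": str(OWL),
    "umls": "http://example.org/umls/cui/",
}

PREFIX_ALIASES = {"vn.role": "role"}


@dataclass(frozen=True)
class NamespaceTable:
    """Prefix -> namespace IRI map used to expand prefixed term values."""

    prefixes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_NAMESPACES))

    def __post_init__(self):
        for prefix, iri in self.prefixes.items():
            if not iri.endswith(("/", "#")):
                raise InvalidInputError(
                    f"namespace {prefix!r} -> {iri!r} must end with '/' or '#'"
                )

    def with_prefix(self, prefix: str, iri: str) -> "NamespaceTable":
        updated = dict(self.prefixes)
        updated[prefix] = iri
        return NamespaceTable(updated)

    def expand(self, value: str) -> str:
        """Expand ``prefix:name`` to a full IRI; full IRIs pass through."""
        if ":" in value:
            prefix, name = value.split(":", 1)
            prefix = PREFIX_ALIASES.get(prefix, prefix)
            if prefix in self.prefixes:
                return self.prefixes[prefix] + name
        return value

    def curie(self, iri: str) -> str:
        """Compact a full IRI to ``prefix:name`` when a namespace matches."""
        best = ""
        best_prefix = None
        for prefix, ns in self.prefixes.items():
            if iri.startswith(ns) and len(ns) > len(best):
                best, best_prefix = ns, prefix
        if best_prefix is None:
            return iri
        return f"{best_prefix}:{iri[len(best):]}"


def _normalize_phrase(phrase: str) -> str:
    return " ".join(phrase.casefold().split())


def mint_local_uri(phrase: str, registry: dict[str, str]) -> str:
    """Deterministic local URI (as a ``local:`` curie) for a phrase.

    The same normalized phrase always mints the same URI, so it can be
    reused across triples; the local name is the phrase's slug.
    """
    normalized = _normalize_phrase(phrase)
    name = slug(normalized)
    if not name:
        raise InvalidPhraseError(f"phrase {phrase!r} normalizes to nothing")
    curie = f"local:{name}"
    registry.setdefault(normalized, curie)
    return registry[normalized]


@dataclass
class KnowledgeGraph:
    """The final triple set with its namespace table and URI registry."""

    triples: list[Triple] = field(default_factory=list)
    namespaces: NamespaceTable = field(default_factory=NamespaceTable)
    uri_registry: dict[str, str] = field(default_factory=dict)

    def distinct_terms(self) -> list[Term]:
        seen: dict[Term, None] = {}
        for t in self.triples:
            for term in (t.subject, t.predicate, t.object):
                seen.setdefault(term)
        return list(seen)


RDFS_LABEL = Term("builtin_uri", "rdfs:label")
OWL_SAMEAS = Term("builtin_uri", "owl:sameAs")


def enrich(
    triples: Sequence[Triple],
    links: Sequence[OntologyLink] = (),
    namespaces: NamespaceTable | None = None,
) -> KnowledgeGraph:
    """Turn extracted triples into a connected, ontology-linked graph.

    Every literal subject/object — and literal (plain-mode) predicate —
    is replaced by its minted local URI; each minted URI receives exactly
    one ``rdfs:label`` triple carrying the original phrase; each link
    whose surface matches a registered phrase adds one ``owl:sameAs``
    triple to the target class.  Linking is optional: with no links a
    plain knowledge graph is still produced.
    """
    namespaces = namespaces or NamespaceTable()
    registry: dict[str, str] = {}
    labels: dict[str, str] = {}

    def to_uri(term: Term) -> Term:
        if term.kind != "literal":
            return term
        curie = mint_local_uri(term.value, registry)
        labels.setdefault(curie, term.value)
        return Term("local_uri", curie)

    out: list[Triple] = []
    for t in triples:
        out.append(
            Triple(
                to_uri(t.subject), to_uri(t.predicate), to_uri(t.object),
                t.provenance, t.sentence_id,
            )
        )
    for curie, phrase in labels.items():
        out.append(
            Triple(Term("local_uri", curie), RDFS_LABEL, Term("literal", phrase), "enrichment")
        )
    for link in links:
        normalized = _normalize_phrase(link.surface)
        curie = registry.get(normalized)
        if curie is None:
            continue
        out.append(
            Triple(
                Term("local_uri", curie), OWL_SAMEAS,
                Term("external_uri", link.class_iri), "link",
            )
        )
    return KnowledgeGraph(out, namespaces, registry)


def _to_rdf_term(term: Term, namespaces: NamespaceTable):
    if term.kind == "literal":
        return RdfLiteral(term.value)
    return URIRef(namespaces.expand(term.value))


def to_rdflib_graph(kg: KnowledgeGraph) -> rdflib.Graph:
    """rdflib view of the graph, binding exactly the namespaces in use."""
    graph = rdflib.Graph(bind_namespaces="none")
    used_prefixes = set()
    for t in kg.triples:
        for term in (t.subject, t.predicate, t.object):
            if term.is_iri and ":" in term.value:
                prefix = term.value.split(":", 1)[0]
                prefix = PREFIX_ALIASES.get(prefix, prefix)
                if prefix in kg.namespaces.prefixes:
                    used_prefixes.add(prefix)
        graph.add(
            (
                _to_rdf_term(t.subject, kg.namespaces),
                _to_rdf_term(t.predicate, kg.namespaces),
                _to_rdf_term(t.object, kg.namespaces),
            )
        )
    for prefix in sorted(used_prefixes):
        graph.bind(prefix, kg.namespaces.prefixes[prefix])
    return graph


def serialize_turtle(kg: KnowledgeGraph) -> str:
    """Standard-conformant Turtle; re-parsing yields the same triple set."""
    return to_rdflib_graph(kg).serialize(format="turtle")


def parse_turtle(text: str) -> set[tuple[str, str, str]]:
    """Parse Turtle back to a set of (s, p, o) IRI/literal strings."""
    graph = rdflib.Graph()
    graph.parse(data=text, format="turtle")
    return {(str(s), str(p), str(o)) for s, p, o in graph}


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export_dot(kg: KnowledgeGraph) -> str:
    """DOT rendering: ellipses for URIs, boxes for literals, one edge per triple."""
    lines = ["digraph knowledge_graph {"]
    endpoints: dict[Term, None] = {}
    for t in kg.triples:
        endpoints.setdefault(t.subject)
        endpoints.setdefault(t.object)
    node_ids: dict[Term, str] = {}
    for term in endpoints:
        node_id = f"n{len(node_ids)}"
        node_ids[term] = node_id
        shape = "ellipse" if term.is_iri else "box"
        lines.append(f'  {node_id} [label="{_dot_escape(term.value)}", shape={shape}];')
    for t in kg.triples:
        lines.append(
            f'  {node_ids[t.subject]} -> {node_ids[t.object]} '
            f'[label="{_dot_escape(t.predicate.value)}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
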