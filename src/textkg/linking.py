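"""Ontology linking: surface terms -> UMLS CUIs -> target-ontology classes.

The funnel has three stages.  Candidate terms are the named-entity
surfaces plus verb lemmas of the annotated sentences.  Each candidate is
matched to a UMLS Concept Unique Identifier through a concept lexicon (a
packaged TSV fixture, or any object with the same ``lookup`` method, e.g.
an adapter over a live biomedical NER stack).  Each CUI is then mapped to
the classes of a target ontology that carry it in a configurable
annotation property, via a SPARQL query over an rdflib graph or a remote
endpoint.  A second, direct-annotator link source can be unioned in
(:func:`combine_link_sets`), which can only grow the link set.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import rdflib
from rdflib import Literal as RdfLiteral, URIRef

from .annotations import SentenceAnnotation
from .errors import IntermediateFormatError, InvalidCombinationError, TextKgError

#: Conventional annotation property carrying UMLS CUIs on ontology classes.
DEFAULT_CUI_PROPERTY = "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#UMLS_CUI"

VERB_POS_PREFIX = "VB"


@dataclass(frozen=True)
class ConceptMapping:
    """A surface term matched to a UMLS concept."""

    surface: str
    lemma: str
    cui: str
    description: str = ""

    def __post_init__(self):
        if not (self.cui.startswith("C") and self.cui[1:].isdigit()):
            raise TextKgError(f"malformed CUI {self.cui!r}")
        if not self.surface:
            raise TextKgError("mapping surface must be non-empty")


@dataclass(frozen=True)
class OntologyLink:
    """A surface term linked to a class of the target ontology."""

    surface: str
    cui: str | None
    class_iri: str
    label: str = ""
    source: str = "umls_sparql"  # umls_sparql | annotator | combined


@dataclass(frozen=True)
class LinkReport:
    """Counts for the three funnel stages; monotonically non-increasing."""

    terms_identified: int
    cuis_found: int
    ontology_links: int

    def __post_init__(self):
        if not (self.ontology_links <= self.cuis_found <= self.terms_identified):
            raise TextKgError(
                "link funnel violated: links <= CUIs <= terms must hold "
                f"({self.ontology_links}, {self.cuis_found}, {self.terms_identified})"
            )


class CuiLexicon:
    """Term -> (CUI, description, score) lexicon with top-score selection.

    Score ties are broken by lexicographic CUI order.
    """

    def __init__(self, entries: Mapping[str, Sequence[tuple[str, str, float]]]):
        self._entries = {
            term.casefold(): sorted(vals, key=lambda v: (-v[2], v[0]))
            for term, vals in entries.items()
        }

    def lookup(self, term: str) -> tuple[str, str] | None:
        """Best (CUI, description) for a term, or None."""
        hits = self._entries.get(" ".join(term.casefold().split()))
        if not hits:
            return None
        cui, description, _ = hits[0]
        return cui, description

    def __len__(self) -> int:
        return len(self._entries)


def load_lexicon_tsv(path: str | Path) -> CuiLexicon:
    """Read a lexicon TSV: ``term<TAB>cui<TAB>description<TAB>score``."""
    entries: dict[str, list[tuple[str, str, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise IntermediateFormatError(path, line_no, "expected 4 tab-separated fields")
            term, cui, description, score = parts
            try:
                entries.setdefault(term, []).append((cui, description, float(score)))
            except ValueError as exc:
                raise IntermediateFormatError(path, line_no, f"bad score {score!r}") from exc
    return CuiLexicon(entries)


def extract_link_candidates(sentences: Iterable[SentenceAnnotation]) -> list[str]:
    """Entity surfaces plus verb lemmas, deduplicated in first-occurrence order.

    Within a sentence, candidates are collected left to right; overlapping
    entity mentions each contribute their own surface (longest first at a
    shared start), but a given surface is listed once document-wide.
    """
    seen: set[str] = set()
    candidates: list[str] = []

    def add(term: str):
        key = " ".join(term.casefold().split())
        if key and key not in seen:
            seen.add(key)
            candidates.append(term)

    for annotation in sentences:
        entities = sorted(
            annotation.entities or (),
            key=lambda e: (e.span.start, -(e.span.end - e.span.start)),
        )
        starts: dict[int, list] = {}
        for mention in entities:
            starts.setdefault(mention.span.start, []).append(mention)
        for i, token in enumerate(annotation.tokens or ()):
            for mention in starts.get(i, ()):
                add(mention.surface)
            if token.pos.startswith(VERB_POS_PREFIX):
                add(token.lemma)
    return candidates


def map_to_umls(
    candidates: Sequence[str], lexicon: CuiLexicon
) -> tuple[list[ConceptMapping], list[str]]:
    """Partition candidates into CUI mappings and unmatched terms."""
    mappings: list[ConceptMapping] = []
    unmatched: list[str] = []
    for term in candidates:
        hit = lexicon.lookup(term)
        if hit is None:
            unmatched.append(term)
        else:
            cui, description = hit
            mappings.append(ConceptMapping(term, term.casefold(), cui, description))
    return mappings, unmatched


class RemoteSparqlEndpoint:
    """Thin SPARQL-SELECT client for a remote endpoint (JSON results).

    Kept deliberately minimal; offline runs use a local rdflib graph
    instead, and tests mock this interface.
    """

    def __init__(self, url: str, timeout: float = 30.0):
        self.url = url
        self.timeout = timeout

    def class_iris_for_cui(self, cui: str, cui_property: str) -> list[str]:
        query = (
            f"SELECT DISTINCT ?cls WHERE {{ ?cls <{cui_property}> ?v . "
            f'FILTER(STR(?v) = "{cui}") }}'
        )
        data = urllib.parse.urlencode({"query": query}).encode()
        request = urllib.request.Request(
            self.url, data=data,
            headers={"Accept": "application/sparql-results+json"},
        )
        with urllib.request.urlopen(request, timeout=self.timeout) as response:
            payload = json.load(response)
        return sorted(
            b["cls"]["value"] for b in payload["results"]["bindings"]
        )


def _as_graph(ontology) -> rdflib.Graph:
    if isinstance(ontology, rdflib.Graph):
        return ontology
    graph = rdflib.Graph()
    graph.parse(str(ontology))
    return graph


def map_cui_to_ontology(cui: str, ontology, cui_property: str = DEFAULT_CUI_PROPERTY) -> list[str]:
    """All class IRIs annotated with the CUI, lexicographically sorted.

    ``ontology`` may be an rdflib Graph, a path to an RDF file, or any
    endpoint object exposing ``class_iris_for_cui``.
    """
    if hasattr(ontology, "class_iris_for_cui"):
        return sorted(ontology.class_iris_for_cui(cui, cui_property))
    graph = _as_graph(ontology)
    result = graph.query(
        "SELECT DISTINCT ?cls WHERE { ?cls ?p ?v . FILTER(STR(?v) = STR(?cui)) }",
        initBindings={"p": URIRef(cui_property), "cui": RdfLiteral(cui)},
    )
    return sorted(str(row[0]) for row in result)


def build_links(
    mappings: Sequence[ConceptMapping],
    ontology,
    cui_property: str = DEFAULT_CUI_PROPERTY,
    source: str = "umls_sparql",
) -> list[OntologyLink]:
    """Resolve every mapping's CUI against the target ontology."""
    graph = ontology if hasattr(ontology, "class_iris_for_cui") else _as_graph(ontology)
    links: list[OntologyLink] = []
    for mapping in mappings:
        for class_iri in map_cui_to_ontology(mapping.cui, graph, cui_property):
            label = ""
            if isinstance(graph, rdflib.Graph):
                label_value = graph.value(URIRef(class_iri), rdflib.RDFS.label)
                label = str(label_value) if label_value is not None else ""
            links.append(OntologyLink(mapping.surface, mapping.cui, class_iri, label, source))
    return links


def _namespace_of(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            return iri.rsplit(sep, 1)[0] + sep
    return iri


def combine_link_sets(
    primary: Sequence[OntologyLink], fallback: Sequence[OntologyLink]
) -> list[OntologyLink]:
    """Union of two link sets, deduplicated on (surface, class IRI).

    Both sets must target the same ontology (judged by shared class-IRI
    namespaces); merged members carry source ``combined``.  The result is
    never smaller than either input.
    """
    ns_primary = {_namespace_of(l.class_iri) for l in primary}
    ns_fallback = {_namespace_of(l.class_iri) for l in fallback}
    if ns_primary and ns_fallback and not (ns_primary & ns_fallback):
        raise InvalidCombinationError(
            f"link sets target different ontologies: {sorted(ns_primary)} vs {sorted(ns_fallback)}"
        )
    seen: set[tuple[str, str]] = set()
    combined: list[OntologyLink] = []
    for link in list(primary) + list(fallback):
        key = (" ".join(link.surface.casefold().split()), link.class_iri)
        if key in seen:
            continue
        seen.add(key)
        combined.append(
            OntologyLink(link.surface, link.cui, link.class_iri, link.label, "combined")
        )
    return combined


def build_link_report(
    candidates: Sequence[str],
    mappings: Sequence[ConceptMapping],
    links: Sequence[OntologyLink],
) -> LinkReport:
    """Funnel counts: terms identified, CUIs found, surfaces linked."""
    linked_surfaces = {" ".join(l.surface.casefold().split()) for l in links}
    mapped_surfaces = {" ".join(m.surface.casefold().split()) for m in mappings}
    return LinkReport(
        terms_identified=len(candidates),
        cuis_found=len(mapped_surfaces),
        ontology_links=len(linked_surfaces & mapped_surfaces),
    )


# Link-table intermediate: TSV (surface, cui, class_iri, label, source).

_LINKS_HEADER = "# surface\tcui\tclass_iri\tlabel\tsource"


def write_links_tsv(links: Iterable[OntologyLink], path: str | Path) -> None:
    lines = [_LINKS_HEADER]
    for l in links:
        lines.append("\t".join([l.surface, l.cui or "", l.class_iri, l.label, l.source]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_links_tsv(path: str | Path) -> list[OntologyLink]:
    links = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise IntermediateFormatError(path, line_no, "expected 5 tab-separated fields")
            surface, cui, class_iri, label, source = parts
            links.append(OntologyLink(surface, cui or None, class_iri, label, source))
    return links
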