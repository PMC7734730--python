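"""Rule-based RDF triple extraction from per-sentence parses.

Two families of triples are produced for every sentence:

*Main triples* come from semantic-role-labeling frames.  In the reified
form the verb surface is the subject and each argument yields one triple
whose predicate is a role URI (``role:Agent``, ``role:Theme``, ...) looked
up in a PropBank/VerbNet-style roleset inventory; argument labels with no
roleset role (``AM-LOC``, ...) fall back to a local URI.  A frame with
arguments A0..An therefore yields exactly n+1 triples.  The plain
(non-reified) form instead emits classic ``(subject, verb, object)``
triples, composing the predicate with the object and a preposition for
locative/temporal modifiers (e.g. ``"warrant attention in"``).

*Secondary triples* come from the dependency parse: chains of
``rdfs:subClassOf`` triples peel noun pre-modifiers (adjectives and noun
compounds) one at a time from the full phrase down to the bare head, and
prepositional constructions ``X of Y`` inside an argument phrase F yield
a pair of local-URI triples anchored at F, which keeps the assembled
graph connected through shared phrases.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotations import SentenceAnnotation, SRLFrame, Span, detokenize
from .errors import IntermediateFormatError, InvalidInputError

TERM_KINDS = frozenset({"literal", "local_uri", "role_uri", "external_uri", "builtin_uri"})

#: Leading tokens stripped from argument phrases: determiners, then
#: auxiliaries when they open the phrase.
DETERMINERS = frozenset({"the", "a", "an", "this", "these", "that", "those"})
AUXILIARIES = frozenset(
    "is are was were be been being will would shall should may might "
    "can could must do does did has have had".split()
)

#: Prepositions participating in the secondary ``X prep Y`` rule.
DEFAULT_PREPOSITIONS = ("of", "in", "for", "with", "on")

#: Dependency relations marking a pre-modifier of a noun, with the term
#: kind each contributes when modifier triples are requested.
PREMODIFIER_RELATIONS = {"amod": "hasAdjective", "compound": "hasCompound"}

#: Dependency relations carrying nominal prepositional attachment.
NOMINAL_PREP_RELATIONS = frozenset({"nmod", "obl"})


@dataclass(frozen=True)
class Term:
    """One position of an RDF triple: a literal or a (prefixed) IRI."""

    kind: str
    value: str

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise InvalidInputError(f"unknown term kind {self.kind!r}")
        if not self.value:
            raise InvalidInputError("term value must be non-empty")
        if self.kind != "literal" and any(ch.isspace() for ch in self.value):
            raise InvalidInputError(f"IRI term contains whitespace: {self.value!r}")

    @property
    def is_iri(self) -> bool:
        return self.kind != "literal"


def literal(value: str) -> Term:
    return Term("literal", value)


def local_uri(name: str) -> Term:
    return Term("local_uri", f"local:{name}")


def role_uri(name: str) -> Term:
    return Term("role_uri", f"role:{name}")


PROVENANCES = frozenset({"main", "main_plain", "secondary", "enrichment", "link"})


@dataclass(frozen=True)
class Triple:
    """An RDF triple with provenance; equality ignores provenance."""

    subject: Term
    predicate: Term
    object: Term
    provenance: str = field(default="main", compare=False)
    sentence_id: int = field(default=0, compare=False)

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise InvalidInputError(f"unknown provenance {self.provenance!r}")

    def spo(self) -> tuple[str, str, str]:
        return (self.subject.value, self.predicate.value, self.object.value)


@dataclass(frozen=True)
class Roleset:
    """One verb sense's argument-label -> role-name map (e.g. confirm.01)."""

    verb_lemma: str
    sense_id: str
    roles: Mapping[str, str]

    def __post_init__(self):
        if not self.sense_id.startswith(self.verb_lemma):
            raise InvalidInputError(
                f"sense id {self.sense_id!r} not prefixed by lemma {self.verb_lemma!r}"
            )


def load_roleset_inventory(path: str | Path) -> dict[str, list[Roleset]]:
    """Read a TSV inventory: ``lemma<TAB>sense_id<TAB>A0=Agent A1=Theme ...``."""
    inventory: dict[str, list[Roleset]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise IntermediateFormatError(path, line_no, "expected 3 tab-separated fields")
            lemma, sense_id, role_spec = parts
            roles = {}
            for pair in role_spec.split():
                if "=" not in pair:
                    raise IntermediateFormatError(path, line_no, f"bad role pair {pair!r}")
                label, name = pair.split("=", 1)
                roles[label] = name
            inventory.setdefault(lemma, []).append(Roleset(lemma, sense_id, roles))
    for senses in inventory.values():
        senses.sort(key=lambda r: r.sense_id)
    return inventory


def strip_phrase(phrase: str, sentence_initial: bool = False) -> str:
    """Drop leading determiners/auxiliaries from a phrase.

    Interior tokens are untouched.  When the phrase opened the sentence,
    a leading capital is folded (acronyms — all-caps words — keep their
    casing).  An all-stopword phrase strips to the empty string; the
    caller decides what to do with it.
    """
    tokens = phrase.split()
    while tokens and tokens[0].lower() in DETERMINERS:
        tokens.pop(0)
    while tokens and tokens[0].lower() in AUXILIARIES:
        tokens.pop(0)
    result = " ".join(tokens)
    if sentence_initial and result:
        first = result.split()[0]
        if first[0].isupper() and not first[1:].isupper():
            result = result[0].lower() + result[1:]
    return result


def resolve_roleset(
    verb_lemma: str,
    argument_labels: Iterable[str],
    inventory: Mapping[str, Sequence[Roleset]],
) -> Roleset | None:
    """First (lowest-numbered) sense whose roles cover the frame's core labels."""
    core = {
        l for l in argument_labels
        if len(l) >= 2 and l[0] == "A" and l[1:].isdigit()
    }
    for roleset in inventory.get(verb_lemma, ()):
        if core <= set(roleset.roles):
            return roleset
    return None


_CORE_LABEL_RE = re.compile(r"^A(\d+)$")


def _label_sort_key(label: str):
    m = _CORE_LABEL_RE.match(label)
    if m:
        return (0, int(m.group(1)), label)
    return (1, 0, label)


def argument_phrase(
    annotation: SentenceAnnotation, label: str, span: Span
) -> tuple[str, str | None]:
    """Stripped text of an argument span, plus any removed leading preposition.

    Modifier arguments (``AM-*``) open with a preposition more often than
    not; it is peeled off here and reported so plain-mode extraction can
    fold it into a composed predicate.
    """
    assert annotation.tokens is not None
    toks = list(annotation.tokens[span.start:span.end])
    prep = None
    if label.startswith("AM-") and toks and toks[0].pos in {"IN", "TO"}:
        prep = toks[0].surface.lower()
        toks = toks[1:]
    text = detokenize([t.surface for t in toks])
    return strip_phrase(text, sentence_initial=span.start == 0), prep


RDFS_SUBCLASS = Term("builtin_uri", "rdfs:subClassOf")


def extract_main_triples(
    annotation: SentenceAnnotation,
    inventory: Mapping[str, Sequence[Roleset]],
    sentence_id: int = 0,
) -> list[Triple]:
    """Reified main triples: one triple per SRL argument.

    The inflected verb surface is the subject; the predicate is the
    roleset role URI when the argument label has one, and a local URI
    naming the bare label otherwise.
    """
    if annotation.srl is None or annotation.tokens is None:
        return []
    triples: list[Triple] = []
    for frame in annotation.srl:
        verb = annotation.tokens[frame.predicate].surface
        roleset = resolve_roleset(frame.predicate_lemma, frame.arguments, inventory)
        for label in sorted(frame.arguments, key=_label_sort_key):
            phrase, _ = argument_phrase(annotation, label, frame.arguments[label])
            if not phrase:
                warnings.warn(f"argument {label} of {verb!r} stripped to nothing; skipped")
                continue
            role = roleset.roles.get(label) if roleset else None
            predicate = role_uri(role) if role else local_uri(label)
            triples.append(Triple(literal(verb), predicate, literal(phrase), "main", sentence_id))
    return triples


def extract_main_triples_plain(
    annotation: SentenceAnnotation,
    inventory: Mapping[str, Sequence[Roleset]] | None = None,
    sentence_id: int = 0,
) -> list[Triple]:
    """Non-reified main triples: ``(A0, verb, A1)`` per frame.

    Each ``AM-*`` argument with a leading preposition *p* adds
    ``(A0, "<verb> <A1> <p>", AM-argument)``.  Frames lacking A0 or A1
    are skipped with a warning.
    """
    if annotation.srl is None or annotation.tokens is None:
        return []
    triples: list[Triple] = []
    for frame in annotation.srl:
        verb = annotation.tokens[frame.predicate].surface
        if "A0" not in frame.arguments or "A1" not in frame.arguments:
            warnings.warn(
                f"frame for {verb!r} lacks A0 or A1; skipped in plain extraction"
            )
            continue
        subj, _ = argument_phrase(annotation, "A0", frame.arguments["A0"])
        obj, _ = argument_phrase(annotation, "A1", frame.arguments["A1"])
        triples.append(
            Triple(literal(subj), literal(verb), literal(obj), "main_plain", sentence_id)
        )
        for label in sorted(frame.arguments, key=_label_sort_key):
            if not label.startswith("AM-"):
                continue
            phrase, prep = argument_phrase(annotation, label, frame.arguments[label])
            if not phrase or prep is None:
                continue
            composed = f"{verb} {obj} {prep}"
            triples.append(
                Triple(literal(subj), literal(composed), literal(phrase),
                       "main_plain", sentence_id)
            )
    return triples


def slug(text: str) -> str:
    """Local-URI name part: lowercase, alphanumerics only, no separators."""
    return "".join(ch for ch in text.lower() if ch.isalnum())


def _premodifier_map(annotation: SentenceAnnotation) -> dict[int, list[tuple[int, str]]]:
    """head token index -> [(modifier index, relation)] for pre-modifiers."""
    premods: dict[int, list[tuple[int, str]]] = {}
    for edge in annotation.dependencies or ():
        if edge.relation in PREMODIFIER_RELATIONS and edge.dependent < edge.head:
            premods.setdefault(edge.head, []).append((edge.dependent, edge.relation))
    for mods in premods.values():
        mods.sort()
    return premods


def _np_phrase(annotation: SentenceAnnotation, head: int,
               premods: Mapping[int, list[tuple[int, str]]]) -> str:
    """Pre-modifiers + head as contiguous text (determiners excluded)."""
    mods = premods.get(head, [])
    start = mods[0][0] if mods else head
    text = annotation.span_text(Span(start, head + 1))
    return strip_phrase(text, sentence_initial=start == 0)


def _containing_argument(
    annotation: SentenceAnnotation, indices: Iterable[int]
) -> tuple[str, Span] | None:
    """Stripped text of the first SRL argument span covering all indices."""
    indices = list(indices)
    for frame in annotation.srl or ():
        for label in sorted(frame.arguments, key=_label_sort_key):
            span = frame.arguments[label]
            if all(span.contains(i) for i in indices):
                phrase, _ = argument_phrase(annotation, label, span)
                if phrase:
                    return phrase, span
    return None


@dataclass(frozen=True)
class PeelStep:
    """One sub-class peel: modifier removed from a phrase."""

    phrase: str
    modifier: str
    relation: str  # amod | compound


def peel_modifier_chains(
    annotation: SentenceAnnotation, sentence_id: int = 0
) -> tuple[list[Triple], list[PeelStep]]:
    """Sub-class chains for every noun with pre-modifiers.

    For k pre-modifiers, exactly k ``rdfs:subClassOf`` triples are
    emitted, removing the leftmost modifier at each step down to the
    bare head (a path, never a branch).
    """
    premods = _premodifier_map(annotation)
    triples: list[Triple] = []
    steps: list[PeelStep] = []
    for head in sorted(premods):
        mods = premods[head]
        for i in range(len(mods)):
            start = mods[i][0]
            parent_start = mods[i + 1][0] if i + 1 < len(mods) else head
            parent_initial = parent_start == 0
            phrase = strip_phrase(
                annotation.span_text(Span(start, head + 1)), sentence_initial=start == 0
            )
            parent = strip_phrase(
                annotation.span_text(Span(parent_start, head + 1)),
                sentence_initial=parent_initial,
            )
            triples.append(
                Triple(literal(phrase), RDFS_SUBCLASS, literal(parent),
                       "secondary", sentence_id)
            )
            mod_surface = annotation.tokens[mods[i][0]].surface
            steps.append(PeelStep(phrase, mod_surface, mods[i][1]))
    return triples, steps


def extract_secondary_triples(
    annotation: SentenceAnnotation,
    main_triples: Sequence[Triple] = (),
    sentence_id: int = 0,
    prepositions: Sequence[str] = DEFAULT_PREPOSITIONS,
) -> list[Triple]:
    """Secondary triples from the dependency parse.

    (a) pre-modifier sub-class chains (see :func:`peel_modifier_chains`);
    (b) for each nominal ``X prep Y`` inside a main-triple argument
    phrase F: ``(F, local:<prep>_<slugY>, X)`` and
    ``(F, local:<slugX>_<prep>, Y)``.
    """
    if annotation.dependencies is None:
        return []
    triples, _ = peel_modifier_chains(annotation, sentence_id)
    premods = _premodifier_map(annotation)
    case_for: dict[int, str] = {}
    for edge in annotation.dependencies:
        if edge.relation == "case":
            case_for[edge.head] = annotation.tokens[edge.dependent].surface.lower()
    prepositions = set(prepositions)
    for edge in annotation.dependencies:
        if edge.relation not in NOMINAL_PREP_RELATIONS:
            continue
        prep = case_for.get(edge.dependent)
        if prep not in prepositions:
            continue
        anchor = _containing_argument(annotation, (edge.head, edge.dependent))
        if anchor is None:
            continue
        f_text, _ = anchor
        x = _np_phrase(annotation, edge.head, premods)
        y = _np_phrase(annotation, edge.dependent, premods)
        if not x or not y:
            continue
        triples.append(
            Triple(literal(f_text), local_uri(f"{prep}_{slug(y)}"), literal(x),
                   "secondary", sentence_id)
        )
        triples.append(
            Triple(literal(f_text), local_uri(f"{slug(x)}_{prep}"), literal(y),
                   "secondary", sentence_id)
        )
    return triples


def emit_modifier_term_triples(
    annotation: SentenceAnnotation, sentence_id: int = 0
) -> list[Triple]:
    """Optional enrichment naming the peeled modifiers themselves.

    Each peel step adds ``(phrase, local:hasAdjective, modifier)`` for an
    adjectival modifier or ``(phrase, local:hasCompound, modifier)`` for a
    noun compound.
    """
    _, steps = peel_modifier_chains(annotation, sentence_id)
    triples = []
    for step in steps:
        predicate = local_uri(PREMODIFIER_RELATIONS[step.relation])
        triples.append(
            Triple(literal(step.phrase), predicate, literal(step.modifier.lower()),
                   "enrichment", sentence_id)
        )
    return triples


# ---------------------------------------------------------------------------
# Intermediate triples file: one triple per line, tab-separated, with kind
# markers; human-editable and re-ingestible.

_TSV_HEADER = "# sentence_id\tprovenance\tsubject_kind\tsubject\tpredicate_kind\tpredicate\tobject_kind\tobject"


def write_triples_tsv(triples: Iterable[Triple], path: str | Path) -> None:
    lines = [_TSV_HEADER]
    for t in triples:
        lines.append(
            "\t".join(
                [
                    str(t.sentence_id), t.provenance,
                    t.subject.kind, t.subject.value,
                    t.predicate.kind, t.predicate.value,
                    t.object.kind, t.object.value,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_triples_tsv(path: str | Path) -> list[Triple]:
    triples = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise IntermediateFormatError(
                    path, line_no, f"expected 8 tab-separated fields, found {len(parts)}"
                )
            sid, prov, sk, sv, pk, pv, ok, ov = parts
            try:
                triples.append(
                    Triple(Term(sk, sv), Term(pk, pv), Term(ok, ov), prov, int(sid))
                )
            except (InvalidInputError, ValueError) as exc:
                raise IntermediateFormatError(path, line_no, str(exc)) from exc
    return triples
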