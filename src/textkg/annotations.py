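"""Linguistic annotations and the pluggable provider contract.

The pipeline never runs an NLP engine directly: every stage consumes
:class:`SentenceAnnotation` objects obtained from an
:class:`AnnotationProvider`.  Two providers are available:

* :class:`ReplayProvider` — replays annotations stored in a JSON fixture,
  byte-reproducibly and fully offline.  This is the provider used by the
  test-suite and by reproducible runs.
* :class:`~textkg.providers.SpacyProvider` — adapter over a spaCy pipeline
  for production use on new text (optional dependency).

Token indices are 0-based and spans are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .errors import CapabilityError, FixtureSchemaError, InvalidInputError, MissingAnnotationError

#: Analysis kinds a provider may be asked for.
ANALYSIS_KINDS = frozenset({"tokens", "constituency", "dependency", "srl", "entities"})

#: Dependency relation used for the sentence root; its head is the
#: pseudo-index -1 (a real token may not head itself).
ROOT_RELATION = "root"


@dataclass(frozen=True)
class Span:
    """Half-open token interval ``[start, end)`` within one sentence."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InvalidInputError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, index: int) -> bool:
        return self.start <= index < self.end


@dataclass(frozen=True)
class Token:
    surface: str
    index: int
    pos: str
    lemma: str

    def __post_init__(self):
        if not self.surface:
            raise InvalidInputError("token surface must be non-empty")


@dataclass(frozen=True)
class ConstituencyNode:
    """A node of a phrase-structure parse; leaves carry exactly one token."""

    label: str
    children: tuple["ConstituencyNode", ...]
    span: Span

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ConstituencyNode"]:
        if self.is_leaf:
            return [self]
        out: list[ConstituencyNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def iter_nodes(self) -> Iterable["ConstituencyNode"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()


@dataclass(frozen=True)
class DependencyEdge:
    head: int
    dependent: int
    relation: str

    def __post_init__(self):
        if self.head == self.dependent:
            raise InvalidInputError("dependency head must differ from dependent")


@dataclass(frozen=True)
class SRLFrame:
    """A predicate (verb) with its labeled argument spans (PropBank labels)."""

    predicate: int
    predicate_lemma: str
    arguments: Mapping[str, Span]

    def __post_init__(self):
        for label, span in self.arguments.items():
            if span.contains(self.predicate):
                raise InvalidInputError(
                    f"argument {label} span contains the predicate token"
                )

    def core_labels(self) -> frozenset[str]:
        """Numbered argument labels (A0, A1, ...) of this frame."""
        return frozenset(
            l for l in self.arguments
            if len(l) >= 2 and l[0] == "A" and l[1:].isdigit()
        )


@dataclass(frozen=True)
class EntityMention:
    span: Span
    surface: str
    candidate_cuis: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        scores = [s for _, s in self.candidate_cuis]
        if scores != sorted(scores, reverse=True):
            raise InvalidInputError("candidate CUI scores must be non-increasing")


@dataclass(frozen=True)
class CorefChain:
    """Mentions of one discourse entity: ``(sentence index, span)`` pairs."""

    mentions: tuple[tuple[int, Span], ...]
    representative: int

    def __post_init__(self):
        if len(self.mentions) < 2:
            raise InvalidInputError("a coreference chain needs at least two mentions")
        if not (0 <= self.representative < len(self.mentions)):
            raise InvalidInputError("representative index out of range")


@dataclass(frozen=True)
class SentenceAnnotation:
    """Bundle of per-sentence analyses; unrequested kinds are ``None``."""

    text: str
    tokens: tuple[Token, ...] | None = None
    constituency: ConstituencyNode | None = None
    dependencies: tuple[DependencyEdge, ...] | None = None
    srl: tuple[SRLFrame, ...] | None = None
    entities: tuple[EntityMention, ...] | None = None

    def token_surfaces(self, span: Span) -> list[str]:
        assert self.tokens is not None
        return [t.surface for t in self.tokens[span.start:span.end]]

    def span_text(self, span: Span) -> str:
        return detokenize(self.token_surfaces(span))


class AnnotationProvider(Protocol):
    """Contract every annotation source satisfies."""

    def analyze_sentence(self, sentence_text: str, requests: Iterable[str]) -> SentenceAnnotation:
        ...


# Punctuation that attaches to the preceding token when detokenizing.
_CLOSING_PUNCT = {".", ",", ";", ":", "!", "?", ")", "]", "}", "%", "''", "'s", "n't"}
_OPENING_PUNCT = {"(", "[", "{", "``"}


def detokenize(tokens: Sequence[str]) -> str:
    """Rebuild a readable phrase from tokens.

    Joins with single spaces, then removes the space before closing
    punctuation/clitics and after opening brackets.
    """
    out: list[str] = []
    for tok in tokens:
        if out and (tok in _CLOSING_PUNCT or tok.startswith("'")):
            out[-1] = out[-1] + tok
        elif out and out[-1] in _OPENING_PUNCT:
            out[-1] = out[-1] + tok
        else:
            out.append(tok)
    return " ".join(out)


def normalize_sentence_key(text: str) -> str:
    """Whitespace-collapsed sentence text; the replay-fixture lookup key."""
    return " ".join(text.split())


def _parse_constituency(node, tokens: list[dict], cursor: list[int], key: str) -> ConstituencyNode:
    """Parse the nested-list tree format ``[label, child, ...]``.

    A leaf is ``[pos, "surface"]``; spans are assigned left to right.
    """
    if not isinstance(node, list) or len(node) < 2 or not isinstance(node[0], str):
        raise FixtureSchemaError(key, f"malformed constituency node: {node!r}")
    label = node[0]
    if len(node) == 2 and isinstance(node[1], str):
        index = cursor[0]
        if index >= len(tokens):
            raise FixtureSchemaError(key, "constituency leaves exceed token count")
        if node[1] != tokens[index]["surface"]:
            raise FixtureSchemaError(
                key, f"leaf {node[1]!r} does not match token {tokens[index]['surface']!r}"
            )
        cursor[0] += 1
        return ConstituencyNode(label, (), Span(index, index + 1))
    children = tuple(_parse_constituency(c, tokens, cursor, key) for c in node[1:])
    return ConstituencyNode(label, children, Span(children[0].span.start, children[-1].span.end))


def _parse_span(raw, n_tokens: int, key: str) -> Span:
    if (not isinstance(raw, list)) or len(raw) != 2:
        raise FixtureSchemaError(key, f"span must be a [start, end] pair, got {raw!r}")
    start, end = raw
    if not (isinstance(start, int) and isinstance(end, int) and 0 <= start < end <= n_tokens):
        raise FixtureSchemaError(key, f"span [{start}, {end}) out of range for {n_tokens} tokens")
    return Span(start, end)


def _parse_entry(key: str, entry: dict) -> SentenceAnnotation:
    if not isinstance(entry, dict) or "tokens" not in entry:
        raise FixtureSchemaError(key, "entry must be an object with a 'tokens' list")
    raw_tokens = entry["tokens"]
    tokens = tuple(
        Token(surface=t["surface"], index=i, pos=t.get("pos", "X"), lemma=t.get("lemma", t["surface"]))
        for i, t in enumerate(raw_tokens)
    )
    n = len(tokens)

    constituency = None
    if "constituency" in entry:
        cursor = [0]
        constituency = _parse_constituency(entry["constituency"], raw_tokens, cursor, key)
        if cursor[0] != n:
            raise FixtureSchemaError(key, "constituency parse does not cover all tokens")

    dependencies = None
    if "dependencies" in entry:
        edges = []
        roots = 0
        for e in entry["dependencies"]:
            head, dep, rel = e["head"], e["dep"], e["rel"]
            if rel == ROOT_RELATION:
                roots += 1
                if head != -1:
                    raise FixtureSchemaError(key, "root edge must use head -1")
            elif not (0 <= head < n):
                raise FixtureSchemaError(key, f"dependency head {head} out of range")
            if not (0 <= dep < n):
                raise FixtureSchemaError(key, f"dependency dependent {dep} out of range")
            edges.append(DependencyEdge(head, dep, rel))
        if roots != 1:
            raise FixtureSchemaError(key, f"expected exactly one root edge, found {roots}")
        dependencies = tuple(edges)

    srl = None
    if "srl" in entry:
        frames = []
        for f in entry["srl"]:
            pred = f["pred"]
            if not (0 <= pred < n):
                raise FixtureSchemaError(key, f"predicate index {pred} out of range")
            args = {}
            for label, raw_span in f.get("args", {}).items():
                if label in args:
                    raise FixtureSchemaError(key, f"duplicate argument label {label}")
                args[label] = _parse_span(raw_span, n, key)
            frames.append(SRLFrame(pred, f.get("lemma", tokens[pred].lemma), args))
        srl = tuple(frames)

    entities = None
    if "entities" in entry:
        mentions = []
        for m in entry["entities"]:
            span = _parse_span(m["span"], n, key)
            surface = detokenize([t.surface for t in tokens[span.start:span.end]])
            cuis = tuple((c, float(s)) for c, s in m.get("cuis", []))
            mentions.append(EntityMention(span, surface, cuis))
        entities = tuple(mentions)

    return SentenceAnnotation(
        text=key,
        tokens=tokens,
        constituency=constituency,
        dependencies=dependencies,
        srl=srl,
        entities=entities,
    )


class ReplayProvider:
    """Annotation provider backed by a JSON fixture.

    The fixture is a top-level map from normalized sentence text to the
    stored analyses.  Replay is deterministic: identical queries return
    structurally identical annotations.
    """

    def __init__(self, annotations: Mapping[str, SentenceAnnotation]):
        self._annotations = dict(annotations)

    @property
    def sentences(self) -> list[str]:
        return list(self._annotations)

    def analyze_sentence(self, sentence_text: str, requests: Iterable[str]) -> SentenceAnnotation:
        requests = set(requests)
        if not sentence_text or not sentence_text.strip():
            raise InvalidInputError("sentence text is empty")
        unknown = requests - ANALYSIS_KINDS
        if unknown:
            raise InvalidInputError(f"unknown analysis kinds: {sorted(unknown)}")
        key = normalize_sentence_key(sentence_text)
        stored = self._annotations.get(key)
        if stored is None:
            raise MissingAnnotationError(key)
        available = {
            "tokens": stored.tokens,
            "constituency": stored.constituency,
            "dependency": stored.dependencies,
            "srl": stored.srl,
            "entities": stored.entities,
        }
        for kind in sorted(requests):
            if available[kind] is None:
                raise CapabilityError(kind)
        return SentenceAnnotation(
            text=stored.text,
            tokens=stored.tokens,
            constituency=stored.constituency if "constituency" in requests else None,
            dependencies=stored.dependencies if "dependency" in requests else None,
            srl=stored.srl if "srl" in requests else None,
            entities=stored.entities if "entities" in requests else None,
        )


def load_replay_fixture(path: str | Path) -> ReplayProvider:
    """Load a replay fixture (JSON) into a deterministic provider."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FixtureSchemaError(str(path), f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise FixtureSchemaError(str(path), "fixture root must be a JSON object")
    annotations = {}
    for key, entry in raw.items():
        annotations[normalize_sentence_key(key)] = _parse_entry(normalize_sentence_key(key), entry)
    return ReplayProvider(annotations)
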