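"""Live annotation provider adapting a spaCy pipeline.

Production runs on new text need a real NLP engine; this adapter maps a
spaCy ``Doc`` onto the :class:`~textkg.annotations.SentenceAnnotation`
contract.  spaCy is an optional dependency (``pip install textkg[live]``);
constituency parses and SRL frames additionally require a pipeline that
provides them (e.g. benepar; an SRL component), otherwise the adapter
raises a :class:`~textkg.errors.CapabilityError` naming the missing kind.

The replay provider, not this adapter, is used for tests and reproducible
runs.
"""

from __future__ import annotations

from typing import Iterable

from .annotations import (
    DependencyEdge,
    EntityMention,
    ROOT_RELATION,
    SentenceAnnotation,
    Span,
    Token,
)
from .errors import CapabilityError, InvalidInputError


class SpacyProvider:
    """Adapter over a loaded spaCy ``Language`` pipeline."""

    def __init__(self, nlp=None, model: str = "en_core_web_sm"):
        if nlp is None:
            try:
                import spacy
            except ImportError as exc:  # pragma: no cover - optional dependency
                raise CapabilityError(
                    "tokens", "spaCy is not installed; install textkg[live] or use a replay fixture"
                ) from exc
            nlp = spacy.load(model)
        self._nlp = nlp

    def analyze_sentence(self, sentence_text: str, requests: Iterable[str]) -> SentenceAnnotation:
        requests = set(requests)
        if not sentence_text or not sentence_text.strip():
            raise InvalidInputError("sentence text is empty")
        for kind in ("constituency", "srl"):
            if kind in requests:
                raise CapabilityError(
                    kind, f"the spaCy adapter does not provide {kind!r}; "
                    "use a pipeline component that does, or a replay fixture"
                )
        doc = self._nlp(sentence_text)
        tokens = tuple(
            Token(surface=t.text, index=i, pos=t.tag_, lemma=t.lemma_)
            for i, t in enumerate(doc)
        )
        dependencies = None
        if "dependency" in requests:
            edges = []
            for i, t in enumerate(doc):
                if t.head.i == i:
                    edges.append(DependencyEdge(-1, i, ROOT_RELATION))
                else:
                    edges.append(DependencyEdge(t.head.i, i, t.dep_))
            dependencies = tuple(edges)
        entities = None
        if "entities" in requests:
            entities = tuple(
                EntityMention(Span(e.start, e.end), e.text, ())
                for e in doc.ents
            )
        return SentenceAnnotation(
            text=sentence_text,
            tokens=tokens if "tokens" in requests or requests else tokens,
            dependencies=dependencies,
            entities=entities,
        )
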