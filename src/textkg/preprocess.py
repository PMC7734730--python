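"""Preprocessing: from raw text to simplified, self-contained sentences.

Four ordered sub-steps, each available as a standalone function:

1. :func:`split_sentences` — rule-based sentence boundary detection.
2. :func:`resolve_coreferences` — substitute pronominal mentions with the
   representative mention of their chain (chains are supplied by the
   caller; chain *discovery* is an annotation-provider concern).
3. :func:`detect_abbreviations` / :func:`expand_abbreviations` — the
   Schwartz–Hearst character-alignment heuristic pairs a parenthesized
   short form with its long-form definition, and every standalone
   occurrence of the short form is replaced document-wide.
4. :func:`simplify_sentence` — split coordinated verb phrases (copying the
   shared subject) and distribute coordinated noun-phrase pre-modifiers
   over their head, so that each output sentence carries one clause.

:func:`preprocess_document` composes the four sub-steps in that fixed
order and records per-sentence provenance.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotations import (
    AnnotationProvider,
    ConstituencyNode,
    CorefChain,
    Span,
    detokenize,
)
from .errors import (
    AmbiguousAbbreviationError,
    CapabilityError,
    MissingAnnotationError,
    ParseMismatchError,
    TextKgError,
)

#: Pronouns (and demonstratives used pronominally) eligible for substitution.
PRONOUN_INVENTORY = frozenset(
    {"it", "its", "they", "them", "their", "this", "these", "that", "those"}
)

#: Terminal punctuation for derived sentences.
TERMINAL = "."

# Word-like tokens (letters/digits with internal hyphens/apostrophes) or
# single punctuation characters.
_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'’\-]*|[^\sA-Za-z0-9]")

# Common abbreviations that end with a period but do not end a sentence.
_NON_TERMINAL_ABBREV = {
    "e.g.", "i.e.", "cf.", "vs.", "etc.", "al.", "dr.", "fig.", "figs.",
    "no.", "st.", "mr.", "mrs.", "ms.", "prof.", "approx.",
}

_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[\"'(\[]?[A-Z0-9])")


def tokenize(text: str) -> list[str]:
    """Split text into word and punctuation tokens (whitespace-free)."""
    return _TOKEN_RE.findall(text)


def split_sentences(document: str) -> list[str]:
    """Split a document into sentences at terminal punctuation.

    Whitespace runs are collapsed; non-whitespace characters are preserved,
    so joining the output with single spaces reproduces the document text
    up to whitespace.  An empty document yields an empty list.
    """
    text = " ".join(document.split())
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        candidate = text[start:match.start()]
        last_word = candidate.rsplit(None, 1)[-1].lower() if candidate.split() else ""
        # Guard: "e.g." and single-initial abbreviations do not end sentences.
        if last_word in _NON_TERMINAL_ABBREV or re.fullmatch(r"[a-z]\.", last_word):
            continue
        sentences.append(candidate)
        start = match.start()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [s.strip() for s in sentences]


def _is_pronominal(tokens: Sequence[str]) -> bool:
    return len(tokens) == 1 and tokens[0].lower() in PRONOUN_INVENTORY


def resolve_coreferences(sentences: Sequence[str], chains: Iterable[CorefChain]) -> list[str]:
    """Replace pronominal mentions with their chain's representative text.

    Chains whose representative is itself pronominal are skipped with a
    warning; sentence count and non-mention text are preserved.
    """
    token_lists = [tokenize(s) for s in sentences]
    # Collect replacements per sentence so spans stay valid until applied.
    replacements: dict[int, list[tuple[Span, list[str]]]] = {}
    for chain in chains:
        rep_sent, rep_span = chain.mentions[chain.representative]
        rep_tokens = token_lists[rep_sent][rep_span.start:rep_span.end]
        if _is_pronominal(rep_tokens):
            warnings.warn(
                f"coreference chain skipped: representative {rep_tokens!r} is pronominal",
                stacklevel=2,
            )
            continue
        for i, (sent_idx, span) in enumerate(chain.mentions):
            if i == chain.representative:
                continue
            mention_tokens = token_lists[sent_idx][span.start:span.end]
            if _is_pronominal(mention_tokens):
                replacements.setdefault(sent_idx, []).append((span, list(rep_tokens)))
    out = []
    for idx, tokens in enumerate(token_lists):
        todo = sorted(replacements.get(idx, ()), key=lambda r: r[0].start, reverse=True)
        new_tokens = list(tokens)
        for span, rep_tokens in todo:
            rep = list(rep_tokens)
            if span.start == 0 and rep:
                rep[0] = rep[0][:1].upper() + rep[0][1:]
            new_tokens[span.start:span.end] = rep
        out.append(detokenize(new_tokens) if todo else sentences[idx])
    return out


@dataclass(frozen=True)
class AbbreviationPair:
    """A (short form, long form) definition found in the text."""

    short_form: str
    long_form: str
    definition_site: tuple[int, Span]

    def __post_init__(self):
        if len(self.short_form) > len(self.long_form):
            raise TextKgError("short form longer than long form")


def _find_best_long_form(short: str, candidate: str) -> str | None:
    """Right-to-left character alignment of the short form onto a candidate.

    Each short-form character must appear in the candidate, in order from
    the right; the first short-form character must start a candidate word.
    Returns the shortest suffix of whole words that aligns, or ``None``.
    """
    s = len(short) - 1
    c = len(candidate) - 1
    while s >= 0:
        ch = short[s].lower()
        if not ch.isalnum():
            s -= 1
            continue
        while c >= 0 and (
            candidate[c].lower() != ch
            or (s == 0 and c > 0 and candidate[c - 1].isalnum())
        ):
            c -= 1
        if c < 0:
            return None
        c -= 1
        s -= 1
    start = candidate.rfind(" ", 0, c + 1) + 1
    return candidate[start:]


def _valid_pair(short: str, long: str) -> bool:
    n_words = len(long.split())
    return (
        any(ch.isalpha() for ch in short)
        and len(short) <= len(long)
        and n_words <= min(len(short) + 5, 2 * len(short))
    )


def detect_abbreviations(sentences: Sequence[str]) -> list[AbbreviationPair]:
    """Find ``long form (SHORT)`` definitions via Schwartz–Hearst alignment."""
    pairs: list[AbbreviationPair] = []
    for sent_idx, sentence in enumerate(sentences):
        tokens = tokenize(sentence)
        for i, tok in enumerate(tokens):
            if tok != "(":
                continue
            try:
                close = tokens.index(")", i + 1)
            except ValueError:
                continue
            inner = tokens[i + 1:close]
            if len(inner) != 1:
                continue  # multi-token parentheticals are not short-form candidates
            short = inner[0]
            if not (2 <= len(short) <= 10) or not any(ch.isalpha() for ch in short):
                continue
            max_words = min(len(short) + 5, 2 * len(short))
            window_start = max(0, i - max_words)
            window = tokens[window_start:i]
            if not window:
                continue
            candidate = detokenize(window)
            long_form = _find_best_long_form(short, candidate)
            if not long_form or not _valid_pair(short, long_form):
                continue
            n_long_tokens = len(tokenize(long_form))
            site = Span(i - n_long_tokens, close + 1)
            pairs.append(AbbreviationPair(short, long_form, (sent_idx, site)))
    return pairs


def expand_abbreviations(
    sentences: Sequence[str], pairs: Sequence[AbbreviationPair]
) -> list[str]:
    """Replace short-form occurrences by their long forms, document-wide.

    The defining parenthetical ``(SHORT)`` is removed; replacement is
    whole-token only.  Conflicting definitions for one short form raise
    :class:`~textkg.errors.AmbiguousAbbreviationError`.
    """
    by_short: dict[str, str] = {}
    for pair in pairs:
        existing = by_short.get(pair.short_form)
        if existing is not None and existing != pair.long_form:
            raise AmbiguousAbbreviationError(
                f"short form {pair.short_form!r} defined as both "
                f"{existing!r} and {pair.long_form!r}"
            )
        by_short[pair.short_form] = pair.long_form
    if not by_short:
        return list(sentences)
    out = []
    for sentence in sentences:
        tokens = tokenize(sentence)
        new_tokens: list[str] = []
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            # Drop a defining/parenthetical "( SHORT )" occurrence entirely.
            if (
                tok == "("
                and i + 2 < len(tokens)
                and tokens[i + 2] == ")"
                and tokens[i + 1] in by_short
            ):
                i += 3
                continue
            if tok in by_short:
                new_tokens.extend(tokenize(by_short[tok]))
            else:
                new_tokens.append(tok)
            i += 1
        out.append(detokenize(new_tokens))
    return out


def _ensure_terminal(text: str) -> str:
    return text if text.endswith((".", "!", "?")) else text + TERMINAL


def _find_vp_coordination(root: ConstituencyNode):
    """Locate ``S -> NP (VP (VP .. CC .. VP))``; return (subject, conjuncts)."""
    for node in root.iter_nodes():
        if not node.label.startswith("S") or node.is_leaf:
            continue
        subject = next((c for c in node.children if c.label == "NP"), None)
        vp = next((c for c in node.children if c.label == "VP"), None)
        if subject is None or vp is None:
            continue
        conjuncts = [c for c in vp.children if c.label == "VP"]
        has_cc = any(c.label == "CC" for c in vp.children)
        if len(conjuncts) >= 2 and has_cc:
            return subject, conjuncts
    return None


def _find_np_premod_coordination(root: ConstituencyNode):
    """Locate an NP of leaves shaped ``mods CC mods head``; return groups."""
    for node in root.iter_nodes():
        if node.label != "NP" or node.is_leaf:
            continue
        if not all(c.is_leaf for c in node.children) or len(node.children) < 4:
            continue
        cc_positions = [i for i, c in enumerate(node.children) if c.label == "CC"]
        if len(cc_positions) != 1:
            continue
        cc = cc_positions[0]
        head = node.children[-1]
        if not head.label.startswith("NN"):
            continue
        group_a = node.children[:cc]
        group_b = node.children[cc + 1:-1]
        if group_a and group_b:
            cc_node = node.children[cc]
            return group_a, group_b, cc_node
    return None


def simplify_sentence(sentence: str, parse: ConstituencyNode) -> list[str]:
    """Split one sentence into smaller ones along coordination boundaries.

    Handles two constructions: verb phrases coordinated under a shared
    subject (the subject is copied into each derived sentence), and
    coordinated pre-modifiers of a shared head noun (each modifier is
    distributed over the head).  Anything else passes through unchanged.
    """
    tokens = tokenize(sentence)
    leaves = parse.leaves()
    if len(leaves) != len(tokens):
        raise ParseMismatchError(
            f"parse has {len(leaves)} leaves but sentence has {len(tokens)} tokens"
        )

    vp = _find_vp_coordination(parse)
    if vp is not None:
        subject, conjuncts = vp
        subj_tokens = tokens[subject.span.start:subject.span.end]
        out = []
        for conj in conjuncts:
            body = tokens[conj.span.start:conj.span.end]
            out.append(_ensure_terminal(detokenize(subj_tokens + body)))
        return out

    np = _find_np_premod_coordination(parse)
    if np is not None:
        group_a, group_b, cc_node = np
        out = []
        for keep, drop in ((group_a, group_b), (group_b, group_a)):
            excluded = {cc_node.span.start}
            excluded.update(i for n in drop for i in range(n.span.start, n.span.end))
            kept = [t for i, t in enumerate(tokens) if i not in excluded and t not in ".!?"]
            out.append(_ensure_terminal(detokenize(kept)))
        return out

    return [_ensure_terminal(sentence)]


@dataclass
class PreprocessedText:
    """Preprocessed sentences plus per-sentence provenance records.

    Each provenance record maps an output sentence to its source sentence
    index/indices and the transforms applied (coref, abbrev, simplify).
    """

    sentences: list[str] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def preprocess_document(
    document: str,
    provider: AnnotationProvider,
    chains: Iterable[CorefChain] = (),
) -> PreprocessedText:
    """Run the full preprocessing chain in its fixed order.

    Order: sentence splitting, coreference substitution, abbreviation
    detection + expansion, then per-sentence simplification using the
    provider's constituency parse.  A sentence the provider cannot parse
    passes through unsimplified with a recorded warning (the intermediate
    file remains editable by hand).
    """
    raw = split_sentences(document)
    result = PreprocessedText()
    if not raw:
        return result

    transforms: list[set[str]] = [set() for _ in raw]

    resolved = resolve_coreferences(raw, chains)
    for i, (a, b) in enumerate(zip(raw, resolved)):
        if a != b:
            transforms[i].add("coref")

    pairs = detect_abbreviations(resolved)
    expanded = expand_abbreviations(resolved, pairs)
    for i, (a, b) in enumerate(zip(resolved, expanded)):
        if a != b:
            transforms[i].add("abbrev")

    for i, sentence in enumerate(expanded):
        try:
            annotation = provider.analyze_sentence(sentence, {"tokens", "constituency"})
            simplified = simplify_sentence(sentence, annotation.constituency)
        except (MissingAnnotationError, CapabilityError) as exc:
            result.warnings.append(f"sentence {i}: not simplified ({exc})")
            simplified = [_ensure_terminal(sentence)]
        applied = set(transforms[i])
        if len(simplified) > 1:
            applied.add("simplify")
        for text in simplified:
            result.sentences.append(text)
            result.provenance.append(
                {"source": [i], "transforms": sorted(applied)}
            )
    return result
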