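"""Preprocessing: splitting, coreference, Schwartz–Hearst, simplification."""

import pytest
from hypothesis import given, strategies as st

from textkg import (
    CorefChain,
    Span,
    detect_abbreviations,
    expand_abbreviations,
    preprocess_document,
    resolve_coreferences,
    simplify_sentence,
    split_sentences,
)
from textkg.errors import AmbiguousAbbreviationError, ParseMismatchError
from textkg.preprocess import tokenize

from conftest import CONFIRMS_LONG, CONJUNCTION, SULCI

PSCI_DOC = (
    "This study confirms the high prevalence of poststroke cognitive impairment "
    "(PSCI) in diverse populations. Prevention strategies are required to reduce "
    "the prevalence of PSCI."
)


# --- sentence splitting ----------------------------------------------------

@pytest.mark.parametrize(
    "document, expected",
    [
        (
            "This study confirms the high prevalence of poststroke cognitive "
            "impairment in diverse populations. It also highlights common risk factors.",
            2,
        ),
        ("Alzheimer's Disease causes dementia.", 1),
        ("", 0),
        ("   \n  ", 0),
        ("Sentences may end abruptly! Or ask questions? Indeed.", 3),
        ("We cite several tools (e.g. parsers and taggers). They help.", 2),
    ],
)
def test_split_sentence_counts(document, expected):
    assert len(split_sentences(document)) == expected


@given(st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd", "Po", "Zs")),
               max_size=120))
def test_split_preserves_non_whitespace(document):
    joined = " ".join(split_sentences(document))
    assert [c for c in joined if not c.isspace()] == [c for c in document if not c.isspace()]


# --- coreference substitution ----------------------------------------------

def test_pronoun_replaced_by_representative():
    sentences = [CONFIRMS_LONG, "It also highlights common risk factors."]
    chain = CorefChain(mentions=((0, Span(0, 2)), (1, Span(0, 1))), representative=0)
    resolved = resolve_coreferences(sentences, [chain])
    assert resolved[0] == sentences[0]
    assert resolved[1] == "This study also highlights common risk factors."


def test_empty_chain_list_is_identity():
    sentences = ["One sentence.", "Another one."]
    assert resolve_coreferences(sentences, []) == sentences


def test_all_pronoun_chain_skipped_with_warning():
    sentences = ["It rains.", "It pours."]
    chain = CorefChain(mentions=((0, Span(0, 1)), (1, Span(0, 1))), representative=0)
    with pytest.warns(UserWarning, match="pronominal"):
        assert resolve_coreferences(sentences, [chain]) == sentences


# --- abbreviation detection (Schwartz–Hearst) ------------------------------

def oracle_long_form(short, window_words):
    """Brute-force oracle: shortest whole-word suffix of the window in which
    the short form's alphanumeric characters occur as a subsequence, with the
    first character starting the suffix's first word."""
    chars = [c.lower() for c in short if c.isalnum()]
    if not chars:
        return None

    def aligns(words):
        text = " ".join(words)
        if not text or text[0].lower() != chars[0]:
            return False
        i = 0
        for ch in text.lower():
            if i < len(chars) and ch == chars[i]:
                i += 1
        return i == len(chars)

    for start in range(len(window_words) - 1, -1, -1):
        if aligns(window_words[start:]):
            return " ".join(window_words[start:])
    return None


CANDIDATES = [
    ("PSCI", "the high prevalence of poststroke cognitive impairment"),
    ("MR", "magnetic resonance"),
    ("AD", "one example is the Alzheimer's Disease"),
    ("UMLS", "the Unified Medical Language System"),
    ("SRL", "semantic role labeling"),
    ("NER", "named entity recognition"),
    ("KGs", "knowledge graphs"),
    ("NCBO", "the National Center for Biomedical Ontology"),
    ("CUI", "a Concept Unique Identifier"),
]


@pytest.mark.parametrize("short, context", CANDIDATES)
def test_detection_agrees_with_alignment_oracle(short, context):
    sentence = f"We consider {context} ({short}) in this text."
    pairs = detect_abbreviations([sentence])
    window = context.split()[-min(len(short) + 5, 2 * len(short)):]
    expected = oracle_long_form(short, window)
    if expected is None:
        assert pairs == []
    else:
        assert len(pairs) == 1
        assert pairs[0].short_form == short
        assert pairs[0].long_form == expected


def test_psci_pair_detected():
    pairs = detect_abbreviations(split_sentences(PSCI_DOC))
    assert [(p.short_form, p.long_form) for p in pairs] == [
        ("PSCI", "poststroke cognitive impairment")
    ]


def test_letterless_parenthetical_rejected():
    assert detect_abbreviations(["in the cohort (2019) we observed decline."]) == []


def test_long_form_word_bound_enforced():
    # 14 words precede the 2-letter short form; no valid 'a'-initial suffix
    # within the 4-word window exists.
    sentence = ("one two three four five six seven eight nine ten eleven twelve "
                "thirteen fourteen (ab) done.")
    assert detect_abbreviations([sentence]) == []


# --- abbreviation expansion -------------------------------------------------

def test_expansion_reproduces_expanded_document():
    sentences = split_sentences(PSCI_DOC)
    pairs = detect_abbreviations(sentences)
    expanded = expand_abbreviations(sentences, pairs)
    assert expanded == [
        "This study confirms the high prevalence of poststroke cognitive "
        "impairment in diverse populations.",
        "Prevention strategies are required to reduce the prevalence of "
        "poststroke cognitive impairment.",
    ]


def test_expansion_is_idempotent():
    sentences = split_sentences(PSCI_DOC)
    pairs = detect_abbreviations(sentences)
    once = expand_abbreviations(sentences, pairs)
    assert expand_abbreviations(once, pairs) == once


def test_empty_pair_list_is_identity():
    sentences = ["Nothing to expand here."]
    assert expand_abbreviations(sentences, []) == sentences


def test_definition_only_occurrence_removes_parenthetical_only():
    sentence = "We measured magnetic resonance (MR) signal."
    pairs = detect_abbreviations([sentence])
    assert expand_abbreviations([sentence], pairs) == ["We measured magnetic resonance signal."]


def test_conflicting_definitions_raise():
    pairs = detect_abbreviations([
        "magnetic resonance (MR) imaging.",
        "the mitral regurgitation (MR) grade.",
    ])
    with pytest.raises(AmbiguousAbbreviationError, match="MR"):
        expand_abbreviations(["any (MR) text."], pairs)


# --- sentence simplification -----------------------------------------------

def test_vp_coordination_splits_with_copied_subject(provider):
    ann = provider.analyze_sentence(CONJUNCTION, {"tokens", "constituency"})
    assert simplify_sentence(CONJUNCTION, ann.constituency) == [
        "This study confirms cognitive impairment in populations.",
        "This study points to ethnoracial differences.",
    ]


def test_np_premodifier_coordination_distributes_over_head(provider):
    ann = provider.analyze_sentence(SULCI, {"tokens", "constituency"})
    simplified = simplify_sentence(SULCI, ann.constituency)
    assert len(simplified) == 2
    assert "clinical interpretation in" in simplified[0]
    assert "biomarker interpretation in" in simplified[1]
    assert all(s.startswith("High-convexity tight sulci may confound") for s in simplified)
    assert all(s.endswith(".") for s in simplified)


def test_sentence_without_conjunction_passes_through(provider):
    sentence = "This study confirms dementia."
    ann = provider.analyze_sentence(sentence, {"tokens", "constituency"})
    assert simplify_sentence(sentence, ann.constituency) == [sentence]


def test_simplification_soundness(provider):
    """Every derived sentence's tokens come from the source plus the copied
    subject/head and terminal punctuation."""
    for sentence in (CONJUNCTION, SULCI):
        ann = provider.analyze_sentence(sentence, {"tokens", "constituency"})
        source = set(tokenize(sentence)) | {"."}
        for derived in simplify_sentence(sentence, ann.constituency):
            assert set(tokenize(derived)) <= source


def test_parse_token_mismatch_raises(provider):
    ann = provider.analyze_sentence(CONJUNCTION, {"tokens", "constituency"})
    with pytest.raises(ParseMismatchError):
        simplify_sentence("A different sentence entirely.", ann.constituency)


# --- full preprocessing chain ----------------------------------------------

def test_preprocess_document_expands_and_keeps_two_sentences(provider):
    result = preprocess_document(PSCI_DOC, provider)
    assert len(result.sentences) == 2
    assert all("poststroke cognitive impairment" in s for s in result.sentences)
    assert all("(" not in s for s in result.sentences)
    assert result.provenance[0]["source"] == [0]
    assert "abbrev" in result.provenance[0]["transforms"]


def test_preprocess_empty_document(provider):
    result = preprocess_document("", provider)
    assert result.sentences == [] and result.provenance == []


def test_preprocess_identity_when_nothing_applies(provider):
    doc = "This study confirms dementia."
    result = preprocess_document(doc, provider)
    assert result.sentences == split_sentences(doc)
    assert result.provenance[0]["transforms"] == []
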