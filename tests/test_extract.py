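"""Triple extraction: reified/plain main triples and dependency secondaries."""

import pytest

from textkg import (
    extract_main_triples,
    extract_main_triples_plain,
    extract_secondary_triples,
    strip_phrase,
)
from textkg.errors import IntermediateFormatError
from textkg.extract import (
    Roleset,
    Term,
    Triple,
    emit_modifier_term_triples,
    literal,
    peel_modifier_chains,
    read_triples_tsv,
    resolve_roleset,
    slug,
    write_triples_tsv,
)

from conftest import CONFIRMS, CONFIRMS_LONG, RISK_FACTORS, WARRANT


def spo_set(triples):
    return {t.spo() for t in triples}


# --- phrase stripping -------------------------------------------------------

@pytest.mark.parametrize(
    "phrase, initial, expected",
    [
        ("the high prevalence of poststroke cognitive impairment", False,
         "high prevalence of poststroke cognitive impairment"),
        ("this study", False, "study"),
        ("This study", True, "study"),
        ("attention", False, "attention"),
        ("Ethnoracial differences", True, "ethnoracial differences"),
        ("the the an a", False, ""),
        ("are required", False, "required"),
    ],
)
def test_strip_phrase(phrase, initial, expected):
    assert strip_phrase(phrase, sentence_initial=initial) == expected


def test_strip_phrase_keeps_acronym_casing():
    assert strip_phrase("MRI scans", sentence_initial=True) == "MRI scans"


# --- roleset resolution -----------------------------------------------------

def test_confirm_resolves_to_lowest_sense(inventory):
    roleset = resolve_roleset("confirm", {"A0", "A1"}, inventory)
    assert roleset.sense_id == "confirm.01"
    assert roleset.roles == {"A0": "Agent", "A1": "Theme"}


def test_modifier_labels_do_not_block_resolution(inventory):
    roleset = resolve_roleset("warrant", {"A0", "A1", "AM-LOC"}, inventory)
    assert roleset.sense_id == "warrant.01"


def test_unknown_verb_resolves_to_none(inventory):
    assert resolve_roleset("zzzfakeverb", {"A0"}, inventory) is None


def test_uncovered_core_labels_fall_through_to_next_sense(inventory):
    roleset = resolve_roleset("confirm", {"A0", "A1", "A2"}, inventory)
    assert roleset.sense_id == "confirm.02"


def test_roleset_sense_must_extend_lemma():
    with pytest.raises(Exception):
        Roleset("confirm", "warrant.01", {"A0": "Agent"})


# --- main triples (reified) -------------------------------------------------

def test_confirms_sentence_yields_printed_reified_triples(provider, inventory):
    ann = provider.analyze_sentence(CONFIRMS, {"tokens", "srl"})
    triples = extract_main_triples(ann, inventory)
    assert [t.spo() for t in triples] == [
        ("confirms", "role:Agent", "study"),
        ("confirms", "role:Theme", "high prevalence of poststroke cognitive impairment"),
    ]
    assert all(t.provenance == "main" for t in triples)
    assert all(t.predicate.kind == "role_uri" for t in triples)


def test_warrant_sentence_orders_core_then_modifier_labels(provider, inventory):
    ann = provider.analyze_sentence(WARRANT, {"tokens", "srl"})
    triples = extract_main_triples(ann, inventory)
    assert [t.spo() for t in triples] == [
        ("warrant", "role:Agent", "ethnoracial differences"),
        ("warrant", "role:Theme", "attention"),
        ("warrant", "local:AM-LOC", "development of prevention strategies"),
    ]
    assert triples[2].predicate.kind == "local_uri"


def test_reified_count_equals_argument_count(provider, inventory):
    """Each SRL argument yields exactly one reified triple."""
    for sentence in (CONFIRMS, CONFIRMS_LONG, WARRANT, RISK_FACTORS):
        ann = provider.analyze_sentence(sentence, {"tokens", "srl"})
        n_args = sum(len(f.arguments) for f in ann.srl)
        assert len(extract_main_triples(ann, inventory)) == n_args


# --- main triples (plain, non-reified) ---------------------------------------

def test_warrant_plain_mode_matches_printed_triples(provider, inventory):
    ann = provider.analyze_sentence(WARRANT, {"tokens", "srl"})
    triples = extract_main_triples_plain(ann, inventory)
    assert [t.spo() for t in triples] == [
        ("ethnoracial differences", "warrant", "attention"),
        ("ethnoracial differences", "warrant attention in",
         "development of prevention strategies"),
    ]
    assert all(t.provenance == "main_plain" for t in triples)


def test_confirms_plain_mode_single_triple(provider, inventory):
    ann = provider.analyze_sentence(CONFIRMS, {"tokens", "srl"})
    assert [t.spo() for t in extract_main_triples_plain(ann, inventory)] == [
        ("study", "confirms", "high prevalence of poststroke cognitive impairment"),
    ]


def test_plain_mode_skips_frames_without_core_pair(provider, inventory):
    sentence = ("Prevention strategies are required to reduce the prevalence of "
                "poststroke cognitive impairment.")
    ann = provider.analyze_sentence(sentence, {"tokens", "srl"})
    with pytest.warns(UserWarning, match="lacks A0 or A1"):
        assert extract_main_triples_plain(ann, inventory) == []


# --- secondary triples -------------------------------------------------------

def test_confirms_secondary_triples_match_printed_set(provider, inventory):
    ann = provider.analyze_sentence(CONFIRMS, {"tokens", "srl", "dependency"})
    secondary = extract_secondary_triples(ann)
    assert spo_set(secondary) == {
        ("high prevalence", "rdfs:subClassOf", "prevalence"),
        ("cognitive impairment", "rdfs:subClassOf", "impairment"),
        ("poststroke cognitive impairment", "rdfs:subClassOf", "cognitive impairment"),
        ("high prevalence of poststroke cognitive impairment",
         "local:of_poststrokecognitiveimpairment", "high prevalence"),
        ("high prevalence of poststroke cognitive impairment",
         "local:highprevalence_of", "poststroke cognitive impairment"),
    }
    assert all(t.provenance == "secondary" for t in secondary)


def test_warrant_secondary_triples_match_printed_set(provider):
    ann = provider.analyze_sentence(WARRANT, {"tokens", "srl", "dependency"})
    assert spo_set(extract_secondary_triples(ann)) == {
        ("prevention strategies", "rdfs:subClassOf", "strategies"),
        ("ethnoracial differences", "rdfs:subClassOf", "differences"),
        ("development of prevention strategies", "local:of_preventionstrategies",
         "development"),
        ("development of prevention strategies", "local:development_of",
         "prevention strategies"),
    }


def test_long_sentence_anchors_prepositions_at_full_theme(provider):
    ann = provider.analyze_sentence(CONFIRMS_LONG, {"tokens", "srl", "dependency"})
    theme = "high prevalence of poststroke cognitive impairment in diverse populations"
    triples = spo_set(extract_secondary_triples(ann))
    assert (theme, "local:of_poststrokecognitiveimpairment", "high prevalence") in triples
    assert (theme, "local:highprevalence_of", "poststroke cognitive impairment") in triples
    assert (theme, "local:in_diversepopulations", "high prevalence") in triples
    assert ("diverse populations", "rdfs:subClassOf", "populations") in triples


def test_peel_chain_is_a_path_of_length_k(provider):
    """k pre-modifiers produce exactly k subClassOf triples forming a path."""
    ann = provider.analyze_sentence(CONFIRMS, {"tokens", "dependency", "srl"})
    chains, steps = peel_modifier_chains(ann)
    subjects = [t.subject.value for t in chains]
    objects = [t.object.value for t in chains]
    assert len(chains) == len(steps) == 3
    # path, no branching: each phrase appears at most once as subject
    assert len(subjects) == len(set(subjects))
    assert "cognitive impairment" in subjects and "cognitive impairment" in objects


def test_secondary_subjects_anchor_to_arguments_or_peels(provider, inventory):
    """Connectivity precondition: secondary subjects are main-argument texts
    or phrases produced by a previous peel."""
    for sentence in (CONFIRMS, CONFIRMS_LONG, WARRANT, RISK_FACTORS):
        ann = provider.analyze_sentence(sentence, {"tokens", "srl", "dependency"})
        main = extract_main_triples(ann, inventory)
        arg_texts = {t.object.value for t in main}
        secondary = extract_secondary_triples(ann, main)
        peel_products = {t.object.value for t in secondary}
        for t in secondary:
            assert t.subject.value in arg_texts | peel_products


def test_bare_noun_produces_no_secondary_triples(provider):
    ann = provider.analyze_sentence("This study confirms dementia.",
                                    {"tokens", "srl", "dependency"})
    assert extract_secondary_triples(ann) == []


# --- modifier-term enrichment triples ----------------------------------------

def test_common_risk_factors_modifier_terms(provider):
    ann = provider.analyze_sentence(RISK_FACTORS, {"tokens", "dependency"})
    assert [t.spo() for t in emit_modifier_term_triples(ann)] == [
        ("common risk factors", "local:hasAdjective", "common"),
        ("risk factors", "local:hasCompound", "risk"),
    ]


def test_diverse_populations_has_adjective(provider):
    ann = provider.analyze_sentence(CONFIRMS_LONG, {"tokens", "dependency"})
    assert ("diverse populations", "local:hasAdjective", "diverse") in {
        t.spo() for t in emit_modifier_term_triples(ann)
    }


def test_bare_nouns_yield_no_modifier_terms(provider):
    ann = provider.analyze_sentence("This study confirms dementia.",
                                    {"tokens", "dependency"})
    assert emit_modifier_term_triples(ann) == []


# --- slug and intermediate format --------------------------------------------

@pytest.mark.parametrize(
    "text, expected",
    [
        ("high prevalence", "highprevalence"),
        ("poststroke cognitive impairment", "poststrokecognitiveimpairment"),
        ("Alzheimer's Disease", "alzheimersdisease"),
    ],
)
def test_slug(text, expected):
    assert slug(text) == expected


def test_triples_tsv_round_trip(tmp_path, provider, inventory):
    ann = provider.analyze_sentence(WARRANT, {"tokens", "srl", "dependency"})
    triples = extract_main_triples(ann, inventory) + extract_secondary_triples(ann)
    path = tmp_path / "triples.tsv"
    write_triples_tsv(triples, path)
    loaded = read_triples_tsv(path)
    assert loaded == triples
    assert [t.provenance for t in loaded] == [t.provenance for t in triples]


def test_malformed_tsv_line_names_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("0\tmain\tliteral\tx\n")
    with pytest.raises(IntermediateFormatError, match=":1:"):
        read_triples_tsv(path)


def test_literal_never_in_predicate_of_printed_roleset_triples(provider, inventory):
    ann = provider.analyze_sentence(CONFIRMS, {"tokens", "srl"})
    for t in extract_main_triples(ann, inventory):
        assert t.predicate.is_iri
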