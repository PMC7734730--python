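# Methods

This note documents the models, rules, and design choices behind textkg,
and what its test fixtures do and do not establish about real text.

## Model

A knowledge graph is a set of RDF triples *t = (s, p, o)*; vertices are
the subjects/objects, edges are the predicates. textkg populates this set
from natural-language sentences using two rule families over standard
linguistic analyses, then links the result to an external ontology.

### Annotation provider contract

The pipeline never invokes an NLP engine directly. It requests analyses
(`tokens`, `constituency`, `dependency`, `srl`, `entities`) from a
provider object. Token indices are 0-based and spans half-open; PoS tags
are Penn-style; dependency edges use UD-style relation names (`amod`,
`compound`, `nmod`, `case`, ...) with the sentence root encoded as an
edge with head −1 (a token may not head itself). The packaged
**ReplayProvider** serves annotations from a JSON fixture keyed by
whitespace-normalized sentence text and is byte-deterministic; the
**SpacyProvider** adapts a live spaCy pipeline and declares, via
capability errors, the kinds it cannot serve (constituency and SRL need
extra pipeline components). Argument strings are rebuilt from tokens by
joining with single spaces and re-attaching punctuation/clitics.

### Preprocessing

Sub-steps run in a fixed order — coreference before abbreviation
expansion before simplification — because each later step assumes the
earlier normalization (a pronoun inside a parenthetical, or an
abbreviation inside a conjunct, would otherwise leak into the output).

* *Sentence splitting* is rule-based: boundaries at `.!?` followed by an
  upper-case/digit opener, with a guard list for common non-terminal
  abbreviations (`e.g.`, `Fig.`, single initials).
* *Coreference substitution* consumes chains supplied by the caller
  (discovery is a provider concern). The pronoun inventory eligible for
  replacement is {it, its, they, them, their, this, these, that, those};
  a chain whose representative is itself pronominal is skipped with a
  warning. Replacements keep the representative's casing, except that a
  sentence-initial replacement is capitalized.
* *Abbreviations* follow the Schwartz–Hearst algorithm: a parenthesized
  short form of 2–10 characters containing a letter is aligned
  right-to-left against the preceding words; the first short-form
  character must start a word; the long-form candidate window is at most
  min(|SF|+5, 2·|SF|) words. Expansion is whole-token and document-wide,
  and the defining parenthetical is removed. Conflicting definitions of
  one short form are an error rather than a silent choice. The test
  suite checks the implementation against a brute-force suffix-alignment
  oracle on a panel of candidate strings.
* *Simplification* handles exactly two constructions, both driven by the
  constituency parse: verb phrases coordinated under a shared subject
  (the subject is copied into one derived sentence per conjunct) and
  coordinated pre-modifiers of a shared noun head (each modifier is
  distributed over the head with the trailing material kept). Deeper
  constructs — relative clauses, appositions — are out of scope in this
  version. Derived sentences are terminated with `.` regardless of the
  source's final mark. A sentence the provider cannot parse passes
  through unsimplified with a recorded warning, keeping the run usable
  and the intermediate editable.

### Main triples (SRL)

Per frame, the inflected verb surface (not the lemma — it is what a
reader sees in the sentence) becomes the subject. The roleset inventory
(TSV: lemma, sense id, label=role pairs) is consulted for the lowest
numbered sense whose labels cover the frame's core labels (A0, A1, ...);
covered labels get `role:<Name>` predicates, uncovered labels (typically
`AM-LOC`, `AM-TMP`) get `local:<LABEL>` predicates. Argument phrases are
stripped of leading determiners and auxiliaries; a leading preposition
is peeled off `AM-*` arguments; a sentence-initial capital is folded
unless the word is an acronym. Triples are ordered A0, A1, A2, then
`AM-*` alphabetically. The `vn.role:` prefix is accepted as an alias of
`role:` so either notation denotes the same IRI.

In **plain (non-reified) mode** each frame instead yields
`(A0, verb, A1)`, plus, per `AM-*` argument with a leading preposition
*p*, a composed-predicate triple `(A0, "<verb> <A1> <p>", AM-arg)`. With
several such arguments the composition rule is applied to each
independently — a generalization of the single documented pattern.
Frames lacking A0 or A1 are skipped with a warning.

### Secondary triples (dependency parse)

Pre-modifiers are the `amod`/`compound` dependents preceding their head.
For a head with k pre-modifiers the chain emits exactly k
`rdfs:subClassOf` triples, peeling the **leftmost** modifier first
(chosen because it produces the most-specific-to-generic path whose
intermediate phrases remain well-formed English); the chain is a path,
never a branch. For nominal prepositional constructions (an `nmod`/`obl`
edge whose `case` token is in the configured preposition list, default
{of, in, for, with, on}), with governor phrase X and dependent phrase Y
inside an SRL argument phrase F, two triples are emitted:
`(F, local:<p>_<slug(Y)>, X)` and `(F, local:<slug(X)>_<p>, Y)`.
Anchoring at F (the same stripped text as the main triple's object for
that argument) is what connects the secondary layer to the main layer.
Slugs are lowercase alphanumerics with no separators. The optional
modifier-term triples (`local:hasAdjective` for `amod` peels,
`local:hasCompound` for `compound` peels) record the material the
sub-class chain would otherwise drop; they take the sentence annotation
as input because the modifier's syntactic kind is not recoverable from
the chain strings alone.

### Ontology linking

Candidates are entity surfaces plus verb lemmas, deduplicated
case-insensitively in first-occurrence order; overlapping mentions each
link once (longest first at a shared start). The lexicon returns the
top-scoring CUI per term, ties broken by lexicographic CUI order. CUIs
are resolved to classes by a SPARQL SELECT over the configured
annotation property (default: the conventional `UMLS_CUI` property IRI
of NCI Thesaurus distributions); results are sorted lexicographically.
The funnel counts (terms ≥ CUIs ≥ linked terms) hold by construction
since each stage filters the previous one. Combining the SPARQL-derived
links with a direct-annotator table is a set union on
(surface, class IRI), so the combined set dominates both sources. The
remote endpoint client is a thin `urllib` wrapper; offline runs use a
local rdflib graph.

### Graph assembly

Phrases are normalized (casefold + whitespace collapse) before minting,
maximizing node reuse and hence connectivity. Verbs and plain-mode
composed predicates are minted like any other phrase, so no literal ever
sits in predicate position of the final graph. Each minted URI carries
exactly one `rdfs:label` with the first-seen original phrase. Each
ontology link whose surface matches a registered phrase adds exactly one
`owl:sameAs` triple to the target class IRI; intermediate UMLS nodes are
not materialized (the CUI is retained in the links TSV). Turtle
serialization goes through rdflib and binds exactly the prefixes in use;
DOT export draws URIs as ellipses, literals as boxes, one labeled edge
per triple.

### Evaluation

Triple equality for set comparison is exact string equality after
normalization: casefold, whitespace collapse, and removal of leading
determiners from subject/object literals. The Jaccard coefficient is
|A∩B| / |A∪B|, defined as 1 when both sets are empty. Report rounding is
two decimals, round-half-even by default; truncation is available
because published comparison tables sometimes truncate (4/37 = 0.108
displays as 0.10 under truncation, 0.11 under rounding).

## Pipeline and reproducibility

There is no randomness anywhere: identical config and inputs produce
byte-identical outputs (asserted by test). Stage skipping compares
modification times: an intermediate newer than its upstream artifact is
consumed instead of recomputed, which implements the expert-review loop
with no extra machinery. The manifest records SHA-256 digests of every
artifact, the config snapshot, and all warnings.

## Fixtures, problem sizes, and limitations

The replay fixture covers eight sentences (the worked examples exercised
throughout the tests), a roleset inventory for their verbs, a synthetic
concept lexicon, and a synthetic nine-class target ontology; problem
sizes in the acceptance script are therefore single sentences and
triple sets of tens of elements, where the rule system's behavior is
exactly checkable. Passing tests show the rules reproduce the intended
analyses given correct parses; they do not show robustness to parser
errors, long coordinated sentences, passive constructions beyond the
fixtures, or real NER/lexicon noise — on live providers, output quality
is bounded by the upstream NLP stack, which is precisely why the
intermediates are editable. Known limitations: no negation or modality
handling, no cross-sentence relations, single-token abbreviation short
forms only, simplification limited to the two constructions above, and
word-sense selection limited to top-score/lowest-sense heuristics.
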