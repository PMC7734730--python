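# textkg

**textkg** builds ontology-linked RDF knowledge graphs from unstructured
scientific text. It is aimed at researchers in biomedical text mining who
want a transparent, rule-based alternative to end-to-end neural systems:
every intermediate artifact is a plain text file that a domain expert can
inspect, hand-edit, and feed back into the pipeline (a *semi-automatic*
workflow).

## What it does

A document moves through four stages:

1. **Preprocessing.** Sentences are split, pronominal coreferences are
   substituted by their representative mention, abbreviations defined as
   `long form (SHORT)` are detected with the Schwartz–Hearst
   character-alignment heuristic and expanded document-wide, and
   coordinated clauses are split into smaller self-contained sentences
   using the constituency parse.
2. **Triple extraction.** For each sentence, *main* triples are derived
   from semantic-role-labeling (SRL) frames. In the reified form, a verb
   *v* with arguments A0..An yields one triple per argument, e.g.

   ```
   ("confirms", role:Agent, "study")
   ("confirms", role:Theme, "high prevalence of poststroke cognitive impairment")
   ```

   where the role names come from a PropBank/VerbNet-style roleset
   inventory (`confirm.01` ⇒ A0:Agent, A1:Theme). *Secondary* triples
   come from the dependency parse: noun pre-modifiers are peeled one at a
   time into `rdfs:subClassOf` chains
   (`"poststroke cognitive impairment" ⊑ "cognitive impairment" ⊑ "impairment"`),
   and nominal `X of Y` constructions yield local-URI relations anchored
   at the enclosing argument phrase.
3. **Ontology linking** (optional). Entity surfaces and verb lemmas are
   mapped to UMLS Concept Unique Identifiers (CUIs) through a concept
   lexicon, and each CUI is resolved to target-ontology classes via a
   SPARQL query over the class-level CUI annotation property. A second,
   direct-annotator link source can be unioned in.
4. **Graph assembly.** Every literal phrase is minted into a
   deterministic local URI (shared phrases become shared nodes, so the
   graph connects), each URI gets an `rdfs:label`, ontology links become
   `owl:sameAs` triples, and the graph is serialized to Turtle and DOT.

Extracted triple sets can be compared against a reference set (e.g. a
manual expert extraction) with `textkg compare`, which reports the set
differences and the Jaccard coefficient
*J(A, B) = |A ∩ B| / |A ∪ B|* over normalized triples.

All linguistic analyses are consumed through a provider contract. The
packaged **replay provider** serves stored annotations from a JSON
fixture, making every run deterministic and fully offline; a spaCy
adapter is available for live annotation of new text
(`pip install textkg[live]`).

## Worked example

```sh
printf 'This study confirms the high prevalence of poststroke cognitive impairment.\n' > doc.txt
textkg run doc.txt --out out \
    --linking \
    --ontology src/textkg/data/synthetic_ontology.ttl \
    --lexicon  src/textkg/data/synthetic_lexicon.tsv
```

prints

```
sentences: 1
triples:   7 {'main': 2, 'secondary': 5}
links:     3
graph:     18 triples -> out/graph.ttl
```

i.e. the sentence yields 2 reified main triples and 5 secondary triples;
3 of the recognized terms were resolved through UMLS CUIs to classes of
the miniature target ontology; and the enriched graph (local URIs +
labels + `owl:sameAs` links) holds 18 triples. `out/` now contains the
editable intermediates (`sentences.txt`, `triples.tsv`, `links.tsv`), the
final `graph.ttl`/`graph.dot`, and a `manifest.json` with SHA-256 digests
of every artifact. Edit `out/triples.tsv` and re-run the same command:
the upstream stages are skipped and the graph reflects your edit.

The packaged lexicon and mini-ontology are synthetic fixtures for
demonstration and testing; point `--ontology`/`--lexicon` at real
resources (e.g. an NCIt file whose classes carry `UMLS_CUI` annotations)
for production use.

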