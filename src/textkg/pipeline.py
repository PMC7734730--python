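"""End-to-end pipeline: preprocess -> extract -> (link) -> assemble.

Every stage writes a human-editable text intermediate (sentences, triples
TSV, links TSV) before the final Turtle/DOT artifacts, and a stage whose
output file is newer than its upstream artifact is skipped on re-run, so
a reviewer can hand-edit any intermediate and resume: the semi-automatic
review loop.  The pipeline is deterministic — identical configuration and
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import extract, linking, preprocess
from .linking import DEFAULT_CUI_PROPERTY
from .annotations import AnnotationProvider, load_replay_fixture
from .errors import TextKgError
from .graph import DEFAULT_NAMESPACES, NamespaceTable, enrich, export_dot, serialize_turtle

SENTENCES_NAME = "sentences.txt"
PROVENANCE_NAME = "sentences.provenance.json"
TRIPLES_NAME = "triples.tsv"
LINKS_NAME = "links.tsv"
TURTLE_NAME = "graph.ttl"
DOT_NAME = "graph.dot"
MANIFEST_NAME = "manifest.json"


def packaged_data(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(importlib.resources.files("textkg") / "data" / name)


class PipelineStageError(TextKgError):
    """A stage failed; carries the stage name and sentence context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; no randomness anywhere."""

    input_path: str | Path
    out_dir: str | Path
    provider: str = "replay"  # replay | live
    fixture_path: str | Path | None = None
    rolesets_path: str | Path | None = None
    linking: bool = False
    ontology_path: str | Path | None = None
    cui_property: str = DEFAULT_CUI_PROPERTY
    lexicon_path: str | Path | None = None
    ontology_prefix: str = "onto"
    reify: bool = True
    modifier_terms: bool = False
    combine_links: bool = False
    annotator_links_path: str | Path | None = None
    prepositions: tuple[str, ...] = extract.DEFAULT_PREPOSITIONS
    rounding: str = "half_even"
    resume: bool = True

    def __post_init__(self):
        if self.linking and (self.ontology_path is None or self.lexicon_path is None):
            raise TextKgError("linking requires an ontology and a lexicon")

    def make_provider(self) -> AnnotationProvider:
        if self.provider == "replay":
            fixture = self.fixture_path or packaged_data("annotations.json")
            return load_replay_fixture(fixture)
        if self.provider == "live":
            from .providers import SpacyProvider

            return SpacyProvider()
        raise TextKgError(f"unknown provider {self.provider!r}")


@dataclass
class RunManifest:
    """Digest of everything a run produced, for reproducibility checks."""

    config: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_intermediate(artifact, path: str | Path) -> None:
    """Serialize an artifact to its line/TSV intermediate format."""
    path = Path(path)
    if isinstance(artifact, preprocess.PreprocessedText):
        path.write_text("".join(s + "\n" for s in artifact.sentences), encoding="utf-8")
    elif isinstance(artifact, (list, tuple)) and all(isinstance(x, str) for x in artifact):
        path.write_text("".join(s + "\n" for s in artifact), encoding="utf-8")
    elif isinstance(artifact, (list, tuple)) and all(
        isinstance(x, extract.Triple) for x in artifact
    ):
        extract.write_triples_tsv(artifact, path)
    elif isinstance(artifact, (list, tuple)) and all(
        isinstance(x, linking.OntologyLink) for x in artifact
    ):
        linking.write_links_tsv(artifact, path)
    else:
        raise TextKgError(f"cannot serialize artifact of type {type(artifact).__name__}")


def read_intermediate(path: str | Path, kind: str):
    """Re-ingest a (possibly hand-edited) intermediate file."""
    path = Path(path)
    if kind == "sentences":
        return [l for l in path.read_text(encoding="utf-8").splitlines() if l.strip()]
    if kind == "triples":
        return extract.read_triples_tsv(path)
    if kind == "links":
        return linking.read_links_tsv(path)
    raise TextKgError(f"unknown intermediate kind {kind!r}")


def _fresh(output: Path, *inputs: Path) -> bool:
    """True when the output exists and is newer than every input."""
    if not output.exists():
        return False
    out_mtime = output.stat().st_mtime_ns
    return all(i.exists() and i.stat().st_mtime_ns < out_mtime for i in inputs)


def _extract_for_sentence(annotation, config: PipelineConfig, inventory, sentence_id: int):
    triples = []
    if config.reify:
        main = extract.extract_main_triples(annotation, inventory, sentence_id)
    else:
        main = extract.extract_main_triples_plain(annotation, inventory, sentence_id)
    triples.extend(main)
    triples.extend(
        extract.extract_secondary_triples(
            annotation, main, sentence_id, config.prepositions
        )
    )
    if config.modifier_terms:
        triples.extend(extract.emit_modifier_term_triples(annotation, sentence_id))
    return triples


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages, honoring hand-edited intermediates.

    Returns a manifest with per-artifact SHA-256 digests, stage counts,
    and any warnings raised along the way.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_path = Path(config.input_path)
    if not input_path.exists():
        raise PipelineStageError("preprocess", f"input {input_path} does not exist")

    manifest = RunManifest()
    manifest.config = {
        k: str(v) if isinstance(v, Path) else v
        for k, v in dataclasses.asdict(config).items()
    }
    provider = config.make_provider()

    sentences_path = out_dir / SENTENCES_NAME
    provenance_path = out_dir / PROVENANCE_NAME
    triples_path = out_dir / TRIPLES_NAME
    links_path = out_dir / LINKS_NAME
    turtle_path = out_dir / TURTLE_NAME
    dot_path = out_dir / DOT_NAME

    # Stage 1: preprocessing.
    if config.resume and _fresh(sentences_path, input_path):
        sentences = read_intermediate(sentences_path, "sentences")
        manifest.stages_skipped.append("preprocess")
    else:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                pre = preprocess.preprocess_document(
                    input_path.read_text(encoding="utf-8"), provider
                )
            manifest.warnings.extend(str(w.message) for w in caught)
            manifest.warnings.extend(pre.warnings)
        except TextKgError as exc:
            raise PipelineStageError("preprocess", str(exc)) from exc
        sentences = pre.sentences
        write_intermediate(pre, sentences_path)
        provenance_path.write_text(
            json.dumps(pre.provenance, indent=2) + "\n", encoding="utf-8"
        )
    manifest.counts["sentences"] = len(sentences)

    # Stage 2: triple extraction.
    inventory = extract.load_roleset_inventory(
        config.rolesets_path or packaged_data("rolesets.tsv")
    )
    annotations = {}
    if config.resume and _fresh(triples_path, sentences_path):
        triples = read_intermediate(triples_path, "triples")
        manifest.stages_skipped.append("triples")
    else:
        triples = []
        for sentence_id, sentence in enumerate(sentences):
            try:
                annotation = provider.analyze_sentence(
                    sentence, {"tokens", "dependency", "srl"}
                )
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    triples.extend(
                        _extract_for_sentence(annotation, config, inventory, sentence_id)
                    )
                manifest.warnings.extend(str(w.message) for w in caught)
                annotations[sentence] = annotation
            except TextKgError as exc:
                raise PipelineStageError(
                    "triples", f"sentence {sentence_id} ({sentence!r}): {exc}"
                ) from exc
        write_intermediate(triples, triples_path)
    by_provenance: dict[str, int] = {}
    for t in triples:
        by_provenance[t.provenance] = by_provenance.get(t.provenance, 0) + 1
    manifest.counts["triples"] = len(triples)
    manifest.counts["triples_by_provenance"] = by_provenance

    # Stage 3: ontology linking (optional).
    links = []
    if config.linking:
        if config.resume and _fresh(links_path, triples_path):
            links = read_intermediate(links_path, "links")
            manifest.stages_skipped.append("linking")
        else:
            try:
                lexicon = linking.load_lexicon_tsv(config.lexicon_path)
                annotated = []
                for sentence_id, sentence in enumerate(sentences):
                    annotated.append(
                        provider.analyze_sentence(sentence, {"tokens", "entities"})
                    )
                candidates = linking.extract_link_candidates(annotated)
                mappings, unmatched = linking.map_to_umls(candidates, lexicon)
                links = linking.build_links(
                    mappings, config.ontology_path, config.cui_property
                )
                if config.combine_links and config.annotator_links_path:
                    fallback = linking.read_links_tsv(config.annotator_links_path)
                    links = linking.combine_link_sets(links, fallback)
                report = linking.build_link_report(candidates, mappings, links)
                manifest.counts["link_report"] = dataclasses.asdict(report)
                manifest.counts["unmatched_terms"] = len(unmatched)
            except TextKgError as exc:
                raise PipelineStageError("linking", str(exc)) from exc
            write_intermediate(links, links_path)
    manifest.counts["links"] = len(links)

    # Stage 4: graph assembly.
    namespaces = NamespaceTable(dict(DEFAULT_NAMESPACES))
    if config.linking and links:
        ns = {linking._namespace_of(l.class_iri) for l in links}
        if len(ns) == 1:
            namespaces = namespaces.with_prefix(config.ontology_prefix, ns.pop())
    try:
        kg = enrich(triples, links, namespaces)
        turtle_path.write_text(serialize_turtle(kg), encoding="utf-8")
        dot_path.write_text(export_dot(kg), encoding="utf-8")
    except TextKgError as exc:
        raise PipelineStageError("graph", str(exc)) from exc
    manifest.counts["graph_triples"] = len(kg.triples)

    for path in (sentences_path, provenance_path, triples_path, links_path,
                 turtle_path, dot_path):
        if path.exists():
            manifest.digests[path.name] = _sha256(path)
    (out_dir / MANIFEST_NAME).write_text(manifest.to_json(), encoding="utf-8")
    return manifest
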