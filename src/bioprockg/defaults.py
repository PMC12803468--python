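"""Bundled default resources: dictionary, ontology, trigger and cue lexica,
and a small worked-example corpus of CHO-glycosylation literature sentences
(cited by PMID; document 99000001 is a synthetic complement covering trace
metals that appear in the graph but not in the quoted sentences)."""

from __future__ import annotations

import io
import json
from importlib import resources as importlib_resources

from .documents import SourceDocument, document_from_json
from .extraction import TriggerLexicon, load_triggers
from .lexicon import Lexicon, load_dictionary
from .ontology import Ontology, load_ontology
from .reltype import CueLexicon, load_cues

_PKG = "bioprockg.resources"


def _text(name: str) -> str:
    return (importlib_resources.files(_PKG) / name).read_text(encoding="utf-8")


def default_lexicon() -> Lexicon:
    return load_dictionary(io.StringIO(_text("dictionary.tsv")))


def default_ontology() -> Ontology:
    return load_ontology(
        io.StringIO(_text("ontology_classes.tsv")),
        io.StringIO(_text("ontology_edges.tsv")),
        io.StringIO(_text("ontology_instances.tsv")),
    )


def default_triggers() -> TriggerLexicon:
    return load_triggers(io.StringIO(_text("triggers.yaml")))


def default_cues() -> CueLexicon:
    return load_cues(io.StringIO(_text("cues.yaml")))


def worked_example_documents() -> list[SourceDocument]:
    return [
        document_from_json(json.loads(line))
        for line in _text("worked_examples.jsonl").splitlines()
        if line.strip()
    ]
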