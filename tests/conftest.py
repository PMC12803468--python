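import pytest

from bioprockg import defaults
from bioprockg.extraction import extract_corpus


@pytest.fixture(scope="session")
def lexicon():
    return defaults.default_lexicon()


@pytest.fixture(scope="session")
def ontology():
    return defaults.default_ontology()


@pytest.fixture(scope="session")
def triggers():
    return defaults.default_triggers()


@pytest.fixture(scope="session")
def cues():
    return defaults.default_cues()


@pytest.fixture(scope="session")
def worked_docs():
    return defaults.worked_example_documents()


@pytest.fixture(scope="session")
def worked_relations(worked_docs, lexicon):
    return extract_corpus(worked_docs, lexicon)


@pytest.fixture(scope="session")
def worked_kg(worked_relations, lexicon, ontology):
    from bioprockg.kg import build_graph
    return build_graph(worked_relations, lexicon, ontology)


def relation_index(relations):
    """(doc, affector, type, affected) tuples for assertion convenience."""
    return {
        (
            r.sentence.doc_id,
            r.affector.concept.canonical_name,
            r.relation_type,
            r.affected.concept.canonical_name,
        )
        for r in relations
    }
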