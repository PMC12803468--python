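# bioprockg

Rule-based text mining and knowledge-graph querying for
biopharmaceutical-manufacturing literature.

Optimizing the glycan profile of a therapeutic protein (a monoclonal
antibody produced in CHO cells, say) means tracking scattered claims of
the form *"manganese increases afucosylation"* or *"elevated osmolality
is associated with an increased apoptosis rate"* across hundreds of
papers. `bioprockg` turns such sentences into structured, queryable
knowledge: it extracts directed **impact relations**
`<Affector, relation-type, Affected>` between process parameters and
product outcomes, normalizes every surface variant ("Mn", "manganese
chloride") to a canonical dictionary concept, files concepts under a
small domain ontology, and assembles everything into a labeled property
graph that answers direct, transitive and class-level questions with
full sentence-level provenance. It is written for bioprocess and
text-mining researchers who want an inspectable, dependency-light
pipeline rather than a hosted service.

## The method

**Extraction.** Trigger words (*cause, affect, regulate, correlate,
increase, ...*) anchor five lexico-syntactic pattern families:

| id | pattern | example |
|----|---------|---------|
| P1 | `<NP> trigger <NP>` (also *results in*, *leads to*) | "Cell death **reduces** productivity" |
| P2 | `<NP> trigger by <NP>` / `<NP> results from <NP>` | "VCD was **caused by** the medium" (direction inverted) |
| P3 | `trigger of <NP> on <NP>` | "the **impact of** media selection **on** glycosylation" |
| P4 | `<NP> is associated/correlates with <NP>` | first argument becomes the Affector |
| P5 | comparison (`lower ... than`, `compared to`) | the compared aspect is linked to the compared entities |

Argument noun phrases are grounded against the dictionary with longest,
token-boundary-aligned matching (a Schwartz–Hearst abbreviation
detector supplies document-local aliases); a noun phrase listing
several concepts expands into one relation per concept.

**Typing.** Each relation gets one of four correlation types from
lexical cues in the two argument phrases and the trigger, in strict
precedence: a negation directly before the trigger ⇒ `not_correlated`;
any negative cue ⇒ `negatively_correlated`; positive cues in ≥ 2
components, or a directionally positive trigger alone ⇒
`positively_correlated`; otherwise `correlated_not_specified`.

**Graph.** Affector/Affected term nodes link to their
`DictionaryConcept` (HAS_CONCEPT), concepts link to ontology classes
(INSTANCE_OF, `is_a`/`role`/`catalyst`/`result` hierarchy), and impact
edges carry merged provenance plus IS_MENTIONED_IN links to
Article/BookChapter nodes. Path queries follow
`Concept ← Affector → [impact] → Affected → Concept`, joining
consecutive steps on the shared concept, up to a degree of separation
of 5.

**Evaluation.** Relation-level scoring against BioC gold annotations:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), overall
and per type, with concept-level entity matching.

A seeded synthetic-corpus generator emits documents instantiating the
five pattern families with gold relations known by construction, so
every stage is testable offline (see `docs/methods.md` for what that
does and does not demonstrate).

## Worked example

```python
from bioprockg import (QuerySpec, build_graph, defaults, extract_corpus,
                       format_path_table, query_paths)

lex = defaults.default_lexicon()          # 30 concepts, COID-identified
onto = defaults.default_ontology()        # 22 classes, four-level is_a DAG
docs = defaults.worked_example_documents()

relations = extract_corpus(docs, lex)     # 28 typed relations
kg = build_graph(relations, lex, onto)

res = query_paths(kg, QuerySpec(affector="manganese", affected="ADCC",
                                max_degree=2))
print(format_path_table(res)[0])
```

prints

```
('manganese —positively_correlated→ afucosylation (30597531) || '
 'afucosylation —positively_correlated→ ADCC (30597531)', '30597531, 30597531')
```

i.e. manganese raises afucosylation and afucosylation raises ADCC
(antibody-dependent cellular cytotoxicity); both steps were mined from
the same article, so its PMID appears once per step in the evidence
column. The scripts in `examples/` walk through extraction, querying
(including the class-level "what trace metals affect glycosylation?"),
synthetic-corpus closure and evaluation, each printing and explaining
its output.

There is also a thin CLI (`bioprockg extract | build-kg | query | eval |
gen-corpus | validate-resources`), e.g.

```bash
bioprockg extract --out relations.jsonl
bioprockg query --relations relations.jsonl \
    --affector manganese --affected ADCC --degree 2
```

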