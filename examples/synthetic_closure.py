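"""Generate a synthetic corpus and verify extraction closure.

The generator writes abstract-like documents whose sentences
instantiate the five pattern families with known gold relations;
running the extractor over them and scoring against the gold checks the
whole pipeline end to end. On these in-scope templates precision and
recall are both 1.0 by design — the corpus measures pipeline
correctness, not real-literature performance.
"""

from bioprockg import (
    GeneratorConfig,
    defaults,
    extract_corpus,
    generate_corpus,
    score_relations,
)

lex = defaults.default_lexicon()
cfg = GeneratorConfig(n_documents=20, seed=42, distractor_rate=0.3)
docs, gold = generate_corpus(cfg, lex)

print(f"generated {len(docs)} documents "
      f"({cfg.sentences_per_doc} sentences each), "
      f"{len(gold)} gold relations")
print("sample sentences:")
for g in gold[:3]:
    print(f"  [{g.relation_type}] {g.sentence_text}")

relations = extract_corpus(docs, lex)
report = score_relations(relations, gold, mode="pair_and_type", lexicon=lex)

print(f"\nextracted {len(relations)} relations")
print(report.to_table())
print("\nPrecision/recall of 1.0 means every generated gold relation was "
      "recovered\nwith the right direction and correlation type, and "
      "nothing else was extracted.")
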