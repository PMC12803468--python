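"""Score predictions against BioC gold annotations.

Writes a small gold set to BioC XML, reads it back (the format used by
annotation tools), scores a prediction list with one deliberate
type error and one miss, and prints the per-type precision/recall/F1
table.
"""

from bioprockg import GoldAnnotation, read_bioc_gold, score_relations, \
    write_bioc_gold
from bioprockg.defaults import default_lexicon

lex = default_lexicon()
gold = [
    GoldAnnotation("30597531", "manganese", "afucosylation",
                   "positively_correlated",
                   "Manganese increased afucosylation of the mAb."),
    GoldAnnotation("20639190", "core fucosylation", "ADCC",
                   "negatively_correlated",
                   "Antibodies lacking core fucosylation show enhanced "
                   "ADCC."),
    GoldAnnotation("27752770", "culture pH", "qp", "not_correlated",
                   "No effects of culture pH on qp could be shown."),
]

bioc_xml = write_bioc_gold(gold)
gold_reread = read_bioc_gold(bioc_xml)
print(f"BioC round trip: wrote and re-read {len(gold_reread)} annotations\n")

predictions = [
    {"doc_id": "30597531", "affector_coid": "COID000001",  # manganese
     "affected_coid": "COID000006",                        # afucosylation
     "relation_type": "positively_correlated"},
    {"doc_id": "20639190", "affector_coid": "COID000009",  # core fucosylation
     "affected_coid": "COID000010",                        # ADCC
     "relation_type": "positively_correlated"},            # wrong type
    # the pH/qp gold relation is not predicted at all -> false negative
]

report = score_relations(predictions, gold_reread, mode="pair_and_type",
                         lexicon=lex)
print(report.to_table())
print("\nThe wrong-type prediction counts as both a false positive (its "
      "own type)\nand a false negative (the gold type); gold terms like "
      "'culture pH' and 'qp'\nare normalized to dictionary concepts before "
      "matching.")
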