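"""Trigger matching, pattern application and end-to-end extraction."""

import pytest

from bioprockg.documents import Sentence
from bioprockg.extraction import (
    apply_patterns,
    extract_document,
    ground_candidates,
    match_triggers,
)
from bioprockg.parse import ShallowParseProvider
from conftest import relation_index

PROVIDER = ShallowParseProvider()


def parse(text):
    return PROVIDER.parse(text)


def candidates(text, triggers):
    ps = parse(text)
    return ps, apply_patterns(ps, match_triggers(ps, triggers))


def make_sentence(text, doc_id="1"):
    return Sentence(sent_id=f"{doc_id}:0:0", text=text,
                    section_title="Abstract", doc_id=doc_id,
                    doc_kind="abstract", start=0, end=len(text))


class TestMatchTriggers:
    def test_simple_impact_trigger(self, triggers):
        ps = parse("N-linked glycosylation affects the potency of proteins.")
        (m,) = match_triggers(ps, triggers)
        assert (m.lemma, m.category, m.negated) == ("affect", "impact", False)

    def test_negated_trigger(self, triggers):
        ps = parse("No effects of culture pH on qp could be shown.")
        m = [t for t in match_triggers(ps, triggers) if t.lemma == "effect"][0]
        assert m.negated

    def test_negation_scope_bounded_by_punctuation(self, triggers):
        ps = parse("with or without uridine, increased galactosylation")
        m = [t for t in match_triggers(ps, triggers)
             if t.lemma == "increase"][0]
        assert not m.negated

    def test_attributive_participles_are_not_triggers(self, triggers):
        ps = parse("an increased apoptosis rate was observed")
        assert match_triggers(ps, triggers) == []

    def test_passive_flag(self, triggers):
        ps = parse("VCD was caused by the medium.")
        m = [t for t in match_triggers(ps, triggers) if t.lemma == "cause"][0]
        assert m.passive

    def test_no_trigger_sentence(self, triggers):
        assert match_triggers(
            parse("Samples were stored frozen until analysis."), triggers
        ) == []


class TestApplyPatterns:
    def test_simple_forward_pattern(self, triggers):
        _, cands = candidates(
            "N-linked glycosylation affects the potency, safety, and "
            "immunogenicity of several therapeutic proteins.", triggers)
        (c,) = cands
        assert c.pattern_id == "P1_simple"
        assert c.affector_np.text == "N-linked glycosylation"
        assert c.affected_np.text.startswith("the potency, safety")

    def test_causal_by_inversion(self, triggers):
        _, cands = candidates(
            "This slightly higher by-product formation for the on-demand "
            "cultures resulted most likely from the marginally higher VCD "
            "which was caused by the more concentrated on-demand medium.",
            triggers)
        by_cand = [c for c in cands if c.trigger.lemma == "cause"][0]
        assert by_cand.pattern_id == "P2_causal_by"
        assert by_cand.affector_np.text == \
            "the more concentrated on-demand medium"
        assert by_cand.affected_np.text == "the marginally higher VCD"

    def test_nominal_of_on_pattern(self, triggers):
        _, cands = candidates(
            "PCA was performed to assess the suitability of using MVDA to "
            "characterize the impact of media selection on antibody "
            "glycosylation and productivity.", triggers)
        (c,) = cands
        assert c.pattern_id == "P3_nominal_of_on"
        assert c.affector_np.text == "media selection"
        assert c.affected_np.text == "antibody glycosylation and productivity"

    def test_comparison_links_aspect_and_enabling_entity(self, triggers):
        _, cands = candidates(
            "This increased sialylation was enabled by a high level of "
            "galactosylation compared to the wild-type antibody.", triggers)
        linked = {
            frozenset((c.affector_np.text, c.affected_np.text))
            for c in cands
        }
        assert frozenset(("this increased sialylation".capitalize(),
                          "a high level of galactosylation")) in linked

    def test_comparison_than_pattern(self, triggers):
        _, cands = candidates(
            "The highest osmolality condition has significantly lower "
            "levels of core fucosylation than the control samples.",
            triggers)
        p5 = [c for c in cands if c.pattern_id == "P5_comparison"]
        assert any(
            "osmolality" in c.affector_np.text
            and "core fucosylation" in c.affected_np.text
            for c in p5
        )

    def test_unmatched_triggers_yield_no_candidates(self, triggers):
        _, cands = candidates("The analysis showed that.", triggers)
        assert cands == []


class TestGroundCandidates:
    def test_cartesian_expansion_over_list_np(self, triggers, lexicon):
        text = ("The analysis showed that pH set points differentially "
                "regulated various intracellular pathways including "
                "intracellular vesicular trafficking, cell cycle, and "
                "apoptosis, thereby resulting in differences in specific "
                "productivity.")
        ps, cands = candidates(text, triggers)
        rels = ground_candidates(cands, lexicon, make_sentence(text))
        assert {
            (r.affector.concept.canonical_name,
             r.affected.concept.canonical_name)
            for r in rels
        } == {("pH", "vesicular trafficking"), ("pH", "cell cycle"),
              ("pH", "apoptosis")}

    def test_ungrounded_side_drops_candidate(self, triggers, lexicon):
        text = "Manganese increased the widget throughput."
        ps, cands = candidates(text, triggers)
        assert ground_candidates(cands, lexicon, make_sentence(text)) == []

    def test_self_relation_dropped(self, triggers, lexicon):
        text = "N-linked glycosylation affects glycosylation."
        ps, cands = candidates(text, triggers)
        assert ground_candidates(cands, lexicon, make_sentence(text)) == []


class TestExtractDocument:
    def test_use_case_one_document(self, worked_relations):
        idx = relation_index(worked_relations)
        assert ("30597531", "manganese", "positively_correlated",
                "afucosylation") in idx
        assert ("30597531", "afucosylation", "positively_correlated",
                "ADCC") in idx

    def test_document_without_grounded_entities_is_empty(self, lexicon):
        from bioprockg.documents import SourceDocument
        doc = SourceDocument("42", "abstract", (
            ("Abstract", "The impeller speed affects foam formation."),))
        assert extract_document(doc, lexicon) == []

    def test_determinism(self, worked_docs, lexicon):
        from bioprockg.extraction import extract_corpus
        a = [r.to_record() for r in extract_corpus(worked_docs, lexicon)]
        b = [r.to_record() for r in extract_corpus(worked_docs, lexicon)]
        assert a == b

    def test_grounding_containment(self, worked_relations):
        """Matched argument texts occur verbatim in the evidence sentence."""
        for r in worked_relations:
            assert r.affector.matched_text in r.sentence.text
            assert r.affected.matched_text in r.sentence.text

    def test_provenance_fields_populated(self, worked_relations):
        for r in worked_relations:
            rec = r.to_record()
            assert rec["doc_id"] and rec["section_title"] and rec["sentence"]
            assert rec["trigger"] and rec["relation_type"]

    def test_abbreviation_alias_grounds_short_form(self, lexicon):
        from bioprockg.documents import SourceDocument
        doc = SourceDocument("77", "abstract", (
            ("Abstract",
             "Cultures received manganese chloride (Mn) on day three. "
             "Mn increased galactosylation of the antibody."),))
        idx = relation_index(extract_document(doc, lexicon))
        assert ("77", "manganese", "positively_correlated",
                "galactosylation") in idx

    def test_section_filter_excludes_references(self, lexicon):
        from bioprockg.documents import SourceDocument
        doc = SourceDocument("88", "article", (
            ("Results", "Manganese increased galactosylation."),
            ("References", "Osmolality increased apoptosis."),
        ))
        idx = relation_index(extract_document(doc, lexicon))
        assert any(t[1] == "manganese" for t in idx)
        assert not any(t[1] == "osmolality" for t in idx)

    def test_provider_failure_is_skipped_not_raised(self, lexicon):
        from bioprockg.documents import SourceDocument

        class FlakyProvider(ShallowParseProvider):
            def parse(self, text):
                if "manganese" in text:
                    raise RuntimeError("boom")
                return super().parse(text)

        doc = SourceDocument("99", "abstract", (
            ("Abstract",
             "Elevated manganese increased galactosylation. "
             "Osmolality increased apoptosis in fed-batch cultures."),))
        rels = extract_document(doc, lexicon, provider=FlakyProvider())
        assert {r.affector.concept.canonical_name for r in rels} == \
            {"osmolality"}

    def test_duplicate_mentions_merge_within_sentence(self, lexicon):
        from bioprockg.documents import SourceDocument
        doc = SourceDocument("55", "abstract", (
            ("Abstract",
             "Manganese chloride and manganese increased galactosylation."),))
        rels = extract_document(doc, lexicon)
        assert len(rels) == 1
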