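"""Impact-relation extraction: triggers, pattern rules, grounding.

Five lexico-syntactic pattern families recover <Affector, Affected> noun
phrase pairs around trigger words:

P1  simple/forward verbal     "<NP> affects/regulates/increases <NP>"
                              (also "results in", "leads to")
P2  causal inversion          "<NP> is caused/enabled by <NP>",
                              "<NP> results from <NP>"
P3  nominal                   "the impact/effect of <NP> on <NP>"
P4  association               "<NP> is associated/correlates with <NP>"
P5  comparison                "<NP> has lower <NP> than <NP>",
                              "... compared to <NP>"

Arguments are then grounded to dictionary concepts (Cartesian expansion
over multi-concept noun phrases); ungrounded candidates and self
relations are dropped; each surviving relation is typed from lexical
cues and carries full sentence/section/document provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, NamedTuple

import yaml

from .documents import Sentence, SourceDocument, segment_sentences
from .errors import ConfigurationError
from .lexicon import (
    ConceptMatch,
    Lexicon,
    collect_document_aliases,
    ground_phrase,
)
from .parse import (
    AUX,
    CONNECTIVES,
    PRONOUNS,
    RELATIVE,
    ParsedSentence,
    ShallowParseProvider,
    is_adverb,
)
from .reltype import CueLexicon, classify, scan_cues
from .textnorm import match_lemma

logger = logging.getLogger(__name__)

TRIGGER_CATEGORIES = ("impact", "causal", "regulation", "association",
                      "comparison")

#: trigger lemmas that also act as nouns in the "<trigger> of X on Y" pattern
NOMINAL_TRIGGERS = {"impact", "effect", "influence"}

#: verbs that link a compared aspect to its subject in P5
_P5_VERBS = {"has", "have", "had", "show", "shows", "showed", "shown",
             "exhibit", "exhibits", "exhibited", "display", "displays",
             "displayed", "demonstrate", "demonstrated", "reveal",
             "revealed", "produce", "produced", "yield", "yielded",
             "is", "are", "was", "were"}

_NEGATION_WINDOW = 3

#: left context marking an -ed participle as attributive (inside an NP,
#: "an increased apoptosis rate") rather than verbal ("X increased Y")
_ATTRIBUTIVE_PREV = {
    "a", "an", "the", "this", "these", "those", "its", "their",
    "of", "in", "to", "with", "for", "by", "on", "from", "as",
    "and", "or", "that", "which", "who",
}

#: generic container nouns whose referents are elaborated by a nearby list
GENERIC_HEADS = {
    "parameter", "parameters", "compound", "compounds", "factor", "factors",
    "condition", "conditions", "component", "components", "additive",
    "additives", "supplement", "supplements", "variable", "variables",
    "agent", "agents", "material", "materials", "metal", "metals",
    "mineral", "minerals", "combination", "combinations",
}


class TriggerLexicon:
    """Configured trigger lemmas, each assigned to one category."""

    def __init__(self, categories: dict[str, Iterable[str]],
                 negation: Iterable[str] = ()):
        self.category_of: dict[str, str] = {}
        for cat, lemmas in categories.items():
            if cat not in TRIGGER_CATEGORIES:
                raise ConfigurationError(f"unknown trigger category {cat!r}")
            for lemma in lemmas:
                self.category_of[lemma] = cat
        self.lemmas = frozenset(self.category_of)
        self.negation = frozenset(negation) or frozenset(
            {"no", "not", "never", "without", "neither", "nor", "cannot"}
        )


def load_triggers(source: str | IO) -> TriggerLexicon:
    """Load the trigger lexicon from YAML ({category: [lemma, ...]})."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    negation = data.pop("negation", ())
    return TriggerLexicon(data, negation)


@dataclass(frozen=True)
class TriggerMatch:
    lemma: str
    category: str
    index: int          # token index in the parsed sentence
    negated: bool = False
    passive: bool = False


class NPSpan(NamedTuple):
    text: str
    start: int  # char offsets within the sentence
    end: int


@dataclass(frozen=True)
class CandidateRelation:
    affector_np: NPSpan
    affected_np: NPSpan
    trigger: TriggerMatch
    pattern_id: str  # P1_simple .. P5_comparison

    def __post_init__(self):
        if self.affector_np == self.affected_np:
            raise ConfigurationError("affector and affected NP must differ")


@dataclass(frozen=True)
class ImpactRelation:
    """A grounded, typed, provenance-carrying impact triple."""

    affector: ConceptMatch
    affected: ConceptMatch
    trigger: str
    relation_type: str | None
    pattern_id: str
    sentence: Sentence
    affector_np: str = ""
    affected_np: str = ""

    def to_record(self) -> dict:
        s = self.sentence
        return {
            "doc_id": s.doc_id,
            "doc_kind": s.doc_kind,
            "chapter_number": s.chapter_number,
            "section_title": s.section_title,
            "sentence": s.text,
            "affector_term": self.affector.matched_text,
            "affector_coid": self.affector.concept.coid,
            "affected_term": self.affected.matched_text,
            "affected_coid": self.affected.concept.coid,
            "trigger": self.trigger,
            "relation_type": self.relation_type,
            "pattern_id": self.pattern_id,
            "affector_type": self.affector.concept.type_name,
            "affected_type": self.affected.concept.type_name,
        }


# ---------------------------------------------------------------------------
# trigger matching

def match_triggers(ps: ParsedSentence, trigger_lexicon: TriggerLexicon
                   ) -> list[TriggerMatch]:
    """One match per trigger token, with negation and passive flags.

    A trigger is negated when a negation token occurs within the three
    tokens preceding it with no intervening punctuation.
    """
    out: list[TriggerMatch] = []
    emitted: set[int] = set()
    toks = ps.tokens
    for i, tok in enumerate(toks):
        if i in ps.masked or not tok.text[0].isalpha():
            continue
        if i > 0 and toks[i - 1].text == "-" and toks[i - 1].end == tok.start:
            continue  # part of a hyphenated compound ("N-linked")
        lemma = match_lemma(tok.text, trigger_lexicon.lemmas)
        if lemma is None:
            continue
        category = trigger_lexicon.category_of[lemma]
        if (
            category == "regulation"
            and tok.low.endswith("ed")
            and _is_attributive(ps, i, emitted)
        ):
            # "an increased apoptosis rate": the directional participle is
            # a cue word inside the NP, not the relation trigger
            continue
        emitted.add(i)
        out.append(
            TriggerMatch(
                lemma=lemma,
                category=category,
                index=i,
                negated=_negated_before(ps, i, trigger_lexicon.negation),
                passive=_is_passive(ps, i),
            )
        )
    return out


def _is_attributive(ps: ParsedSentence, i: int, trigger_idx: set[int]
                    ) -> bool:
    j = i - 1
    while j >= 0 and is_adverb(ps.tokens[j].text):
        j -= 1
    if j < 0:
        return True
    # the object of a trigger verb ("controls reduced X") is an NP too
    return ps.tokens[j].low in _ATTRIBUTIVE_PREV or j in trigger_idx


def _negated_before(ps: ParsedSentence, i: int, negation) -> bool:
    for j in range(i - 1, max(-1, i - 1 - _NEGATION_WINDOW), -1):
        tok = ps.tokens[j]
        if not tok.text[0].isalnum():
            return False  # punctuation bounds the negation scope
        if tok.low in negation:
            return True
    return False


def _is_passive(ps: ParsedSentence, i: int) -> bool:
    tok = ps.tokens[i]
    looks_participial = tok.low.endswith("ed") or tok.low.endswith("en")
    if not looks_participial:
        return False
    for j in range(i - 1, max(-1, i - 3), -1):
        if ps.tokens[j].low in AUX:
            return True
        if not is_adverb(ps.tokens[j].text):
            break
    return False


# ---------------------------------------------------------------------------
# argument-span location

def _next_content(ps: ParsedSentence, i: int, max_skip: int = 3
                  ) -> tuple[int, str] | None:
    """First non-adverb token after i (skipping at most max_skip)."""
    skipped = 0
    j = i + 1
    n = len(ps.tokens)
    while j < n and skipped <= max_skip:
        tok = ps.tokens[j]
        if j in ps.masked or is_adverb(tok.text):
            j += 1
            skipped += 1
            continue
        return j, tok.low
    return None


def _is_comma_boundary(ps: ParsedSentence, j: int) -> bool:
    toks = ps.tokens
    if toks[j].text != ",":
        return False
    if j + 1 >= len(toks):
        return True
    nxt = toks[j + 1].low
    return nxt in CONNECTIVES or nxt in PRONOUNS


def _is_and_boundary(ps: ParsedSentence, j: int) -> bool:
    toks = ps.tokens
    if toks[j].low not in ("and", "or"):
        return False
    return j + 1 < len(toks) and toks[j + 1].low in AUX


_LEFT_SKIP = AUX | {"not", "to", "that", "which", "who"}


def _left_np(ps: ParsedSentence, i: int, boundaries: set[int]
             ) -> NPSpan | None:
    """Noun-phrase span left of token i (the subject-side argument).

    Auxiliaries, adverbs and relative markers adjacent to the trigger are
    skipped; collection then runs until a clause boundary. If collection
    stops at another trigger that heads a relative clause
    ("NP that inhibits X ... TRIGGER"), the relative clause's content is
    discarded and collection resumes with the outer subject NP.
    """
    toks = ps.tokens
    j = i - 1
    # skip phase
    while j >= 0 and (
        j in ps.masked or toks[j].low in _LEFT_SKIP or is_adverb(toks[j].text)
    ):
        j -= 1
    collected: list[int] = []
    while j >= 0:
        tok = toks[j]
        if j in boundaries:
            rel = _relative_marker_before(ps, j)
            if rel is not None:
                collected.clear()  # drop the relative clause's material
                j = rel - 1
                continue
            break
        if j in ps.masked:
            if collected:
                break
            j -= 1
            continue
        if tok.low in AUX or tok.low in RELATIVE or tok.low in ("than",
                                                                "compared"):
            break
        if _is_comma_boundary(ps, j) or _is_and_boundary(ps, j):
            break
        collected.append(j)
        j -= 1
    return _span_from(ps, collected)


def _relative_marker_before(ps: ParsedSentence, t: int) -> int | None:
    """Index of a that/which immediately heading trigger token t, if any."""
    j = t - 1
    hops = 0
    while j >= 0 and hops < 3:
        low = ps.tokens[j].low
        if low in ("that", "which"):
            return j
        if low in AUX or is_adverb(ps.tokens[j].text):
            j -= 1
            hops += 1
            continue
        return None
    return None


def _right_np(ps: ParsedSentence, i: int, boundaries: set[int],
              skip: tuple[str, ...] = ()) -> NPSpan | None:
    """Noun-phrase span right of token i (the object-side argument)."""
    toks = ps.tokens
    n = len(toks)
    j = i + 1
    # skip phase: adverbs and pattern particles
    while j < n and (
        j in ps.masked or toks[j].low in skip or is_adverb(toks[j].text)
    ):
        j += 1
    collected: list[int] = []
    while j < n:
        tok = toks[j]
        if j in boundaries:
            break
        if j in ps.masked:
            if collected:
                break
            j += 1
            continue
        if tok.low in AUX or tok.low in RELATIVE or tok.low in ("than",
                                                                "compared"):
            break
        if _is_comma_boundary(ps, j) or _is_and_boundary(ps, j):
            break
        collected.append(j)
        j += 1
    return _span_from(ps, collected)


def _span_from(ps: ParsedSentence, indices: list[int]) -> NPSpan | None:
    content = [k for k in indices if any(c.isalnum() for c in ps.tokens[k].text)]
    if not content:
        return None
    a, b = min(indices), max(indices)
    # trim leading/trailing punctuation-only tokens
    while not any(c.isalnum() for c in ps.tokens[a].text):
        a += 1
    while not any(c.isalnum() for c in ps.tokens[b].text):
        b -= 1
    return NPSpan(ps.span_text(a, b), ps.tokens[a].start, ps.tokens[b].end)


# ---------------------------------------------------------------------------
# pattern application

def apply_patterns(ps: ParsedSentence, triggers: list[TriggerMatch]
                   ) -> list[CandidateRelation]:
    """Apply the five pattern families to the matched triggers."""
    toks = ps.tokens
    n = len(toks)

    # first pass: structural plan per trigger, so every trigger/particle
    # token is a boundary for every other trigger's argument spans
    boundaries: set[int] = set()
    plans: list[tuple[TriggerMatch, str, dict]] = []
    for t in triggers:
        if t.category == "comparison":
            boundaries.add(t.index)
            continue
        i = t.index
        boundaries.add(i)
        nxt = _next_content(ps, i)
        plan: dict = {}
        kind = "P1"
        if (
            t.lemma in NOMINAL_TRIGGERS
            and nxt is not None
            and nxt[1] == "of"
        ):
            of_idx = nxt[0]
            on_idx = None
            for j in range(of_idx + 1, n):
                low = toks[j].low
                if low == "on":
                    on_idx = j
                    break
                if low in (":", ";") or toks[j].low in AUX:
                    break
                if _is_comma_boundary(ps, j):
                    break
            if on_idx is not None:
                kind = "P3"
                plan = {"of": of_idx, "on": on_idx}
                boundaries.update((of_idx, on_idx))
        if kind != "P3":
            particle = None
            if nxt is not None and nxt[1] in ("by", "from", "to", "in",
                                              "with", "of", "on"):
                particle = nxt
            looks_past = toks[i].low.endswith("ed") or toks[i].low.endswith("en")
            consumed = False
            if particle and particle[1] == "by" and (t.passive or looks_past):
                kind = "P2"
                consumed = True
            elif t.lemma == "result" and particle and particle[1] == "from":
                kind = "P2"
                consumed = True
            elif t.lemma == "result" and particle and particle[1] == "in":
                kind = "P1"
                consumed = True
            elif t.lemma == "lead" and particle and particle[1] == "to":
                kind = "P1"
                consumed = True
            elif t.category == "association":
                if nxt is not None and nxt[1] == "that":
                    kind = "skip"  # clausal complement, no NP argument
                else:
                    kind = "P4"
                    consumed = bool(particle) and particle[1] in ("with",
                                                                  "to", "in")
            else:
                if nxt is not None and nxt[1] == "that":
                    kind = "skip"
            # an unconsumed particle ("affects by-product formation") is
            # ordinary NP material, not a span boundary
            if particle and consumed:
                boundaries.add(particle[0])
                plan["particle"] = particle
        plans.append((t, kind, plan))

    for j, tok in enumerate(toks):
        if tok.text in (":", ";"):
            boundaries.add(j)

    out: list[CandidateRelation] = []
    for t, kind, plan in plans:
        i = t.index
        if kind == "skip":
            continue
        if kind == "P3":
            of_idx, on_idx = plan["of"], plan["on"]
            affector = _span_from(ps, list(range(of_idx + 1, on_idx)))
            affected = _right_np(ps, on_idx, boundaries)
            _emit(out, affector, affected, t, "P3_nominal_of_on")
        elif kind == "P2":
            particle = plan["particle"]
            affected = _left_np(ps, i, boundaries)
            affector = _right_np(ps, particle[0], boundaries)
            _emit(out, affector, affected, t, "P2_causal_by")
        elif kind == "P4":
            particle = plan.get("particle")
            affector = _left_np(ps, i, boundaries)
            skip = (particle[1],) if particle else ("with", "to", "in")
            affected = _right_np(ps, i, boundaries, skip=skip)
            _emit(out, affector, affected, t, "P4_association")
        else:  # P1
            particle = plan.get("particle")
            affector = _left_np(ps, i, boundaries)
            start = particle[0] if particle and particle[1] in ("in", "to") \
                else i
            affected = _right_np(ps, start, boundaries)
            _emit(out, affector, affected, t, "P1_simple")

    out.extend(_comparison_candidates(ps, triggers, boundaries))
    out.sort(key=lambda c: (c.trigger.index, c.affector_np.start))
    return out


def _emit(out, affector, affected, trigger, pattern_id):
    if affector is None or affected is None:
        return
    if affector == affected:
        return
    out.append(
        CandidateRelation(
            affector_np=affector,
            affected_np=affected,
            trigger=trigger,
            pattern_id=pattern_id,
        )
    )


def _comparison_candidates(ps: ParsedSentence, triggers, boundaries
                           ) -> list[CandidateRelation]:
    """P5: link a compared aspect to the compared entities.

    ``<subject> has lower <aspect> than <entity>`` relates the aspect to
    the subject and to the than/compared-to entity; ungrounded entities
    simply drop at the grounding stage.
    """
    toks = ps.tokens
    out: list[CandidateRelation] = []
    comp_triggers = {t.index: t for t in triggers
                     if t.category == "comparison"}

    def mk_trigger(idx: int, lemma: str) -> TriggerMatch:
        return comp_triggers.get(
            idx, TriggerMatch(lemma=lemma, category="comparison", index=idx)
        )

    for j, tok in enumerate(toks):
        if j in ps.masked:
            continue
        if tok.low == "compared" and j + 1 < len(toks) and \
                toks[j + 1].low in ("to", "with"):
            aspect = _left_np(ps, j, boundaries)
            entity = _right_np(ps, j + 1, boundaries)
            trig = mk_trigger(j, "compare")
            if aspect and entity and aspect != entity:
                out.append(CandidateRelation(entity, aspect, trig,
                                             "P5_comparison"))
        elif tok.low == "than":
            verb = None
            k = j - 1
            while k >= 0 and k not in boundaries:
                if toks[k].low in _P5_VERBS:
                    verb = k
                    break
                if _is_comma_boundary(ps, k) or toks[k].text in (":", ";"):
                    break
                k -= 1
            if verb is None:
                continue
            aspect = _span_from(ps, list(range(verb + 1, j)))
            subject = _left_np(ps, verb, boundaries)
            entity = _right_np(ps, j, boundaries)
            trig = mk_trigger(j, "than")
            for affector in (subject, entity):
                if affector and aspect and affector != aspect:
                    out.append(CandidateRelation(affector, aspect, trig,
                                                 "P5_comparison"))
    return out


# ---------------------------------------------------------------------------
# grounding

def ground_candidates(cands: Iterable[CandidateRelation], lex: Lexicon,
                      sentence: Sentence, doc_id: str | None = None
                      ) -> list[ImpactRelation]:
    """Ground candidate NP pairs to concepts (Cartesian expansion).

    Candidates whose noun phrase grounds to nothing are dropped, as are
    relations whose two sides ground to the same concept.
    """
    out: list[ImpactRelation] = []
    for cand in cands:
        aff_matches = ground_phrase(lex, cand.affector_np.text, doc_id)
        afd_matches = ground_phrase(lex, cand.affected_np.text, doc_id)
        for a in aff_matches:
            for b in afd_matches:
                if a.concept.coid == b.concept.coid:
                    continue
                out.append(
                    ImpactRelation(
                        affector=a,
                        affected=b,
                        trigger=cand.trigger.lemma,
                        relation_type=None,
                        pattern_id=cand.pattern_id,
                        sentence=sentence,
                        affector_np=cand.affector_np.text,
                        affected_np=cand.affected_np.text,
                    )
                )
    return out


_PAREN_LIST_RE = re.compile(r"\(([^()]*,[^()]*,[^()]*)\)")


def _elaborate_generic(cand: CandidateRelation, ps: ParsedSentence,
                       lex: Lexicon, doc_id: str | None
                       ) -> CandidateRelation:
    """Resolve generic container subjects through elaboration lists.

    "three process parameters ...: A, B, and C" or "compounds to increase
    X (A, B, C)" name their referents in a trailing colon list or a
    parenthesized list; when the affector NP has a generic head and no
    dictionary hit, the list text stands in for it (and a parenthesized
    list is removed from the affected NP it trails).
    """
    aff_text = cand.affector_np.text
    words = {w.lower().strip(".,;") for w in aff_text.split()}
    if not (words & GENERIC_HEADS):
        return cand
    if ground_phrase(lex, aff_text, doc_id):
        return cand
    m = re.search(r":\s+(.+)$", ps.text)
    if m and "," in m.group(1):
        new_affector = NPSpan(m.group(1).rstrip(". "), m.start(1),
                              m.start(1) + len(m.group(1).rstrip(". ")))
        return dataclasses.replace(cand, affector_np=new_affector)
    for pm in _PAREN_LIST_RE.finditer(ps.text):
        near_affected = (
            pm.start() >= cand.affected_np.start - 1
            and pm.start() <= cand.affected_np.end + 2
        )
        if near_affected:
            inner = pm.group(1)
            new_affector = NPSpan(inner, pm.start(1), pm.end(1))
            affected_text = (
                cand.affected_np.text.replace(pm.group(0), " ").strip()
                or cand.affected_np.text
            )
            new_affected = NPSpan(affected_text, cand.affected_np.start,
                                  cand.affected_np.end)
            return dataclasses.replace(cand, affector_np=new_affector,
                                       affected_np=new_affected)
    return cand


# ---------------------------------------------------------------------------
# full pipeline

def _trigger_context(ps: ParsedSentence, t: TriggerMatch) -> str:
    """Adverbs adjacent to the trigger ("correlates positively with")."""
    parts: list[str] = []
    j = t.index - 1
    while j >= 0 and is_adverb(ps.tokens[j].text):
        parts.append(ps.tokens[j].text)
        j -= 1
    parts.reverse()
    j = t.index + 1
    while j < len(ps.tokens) and is_adverb(ps.tokens[j].text):
        parts.append(ps.tokens[j].text)
        j += 1
    return " ".join(parts)


def extract_sentence(sentence: Sentence, lex: Lexicon,
                     provider, trigger_lexicon: TriggerLexicon,
                     cues: CueLexicon,
                     directional_trigger_extension: bool = True
                     ) -> list[ImpactRelation]:
    """Run triggers -> patterns -> grounding -> typing on one sentence."""
    ps = provider.parse(sentence.text)
    triggers = match_triggers(ps, trigger_lexicon)
    if not triggers:
        return []
    cands = apply_patterns(ps, triggers)
    relations: list[ImpactRelation] = []
    for cand in cands:
        cand = _elaborate_generic(cand, ps, lex, sentence.doc_id)
        grounded = ground_candidates([cand], lex, sentence, sentence.doc_id)
        if not grounded:
            continue
        cues_found = scan_cues(
            cand.affector_np.text,
            cand.affected_np.text,
            cand.trigger.lemma,
            trigger_context=_trigger_context(ps, cand.trigger),
            cues=cues,
            trigger_negated=cand.trigger.negated,
        )
        rtype = classify(cues_found, directional_trigger_extension)
        relations.extend(
            dataclasses.replace(r, relation_type=rtype) for r in grounded
        )
    # merge duplicates: one relation per (affector, affected, trigger)
    seen: set[tuple] = set()
    unique: list[ImpactRelation] = []
    for r in relations:
        key = (r.affector.concept.coid, r.affected.concept.coid, r.trigger)
        if key in seen:
            continue
        seen.add(key)
        unique.append(r)
    return unique


def extract_document(doc: SourceDocument, lex: Lexicon, ontology=None,
                     provider=None, trigger_lexicon=None, cues=None,
                     include_sections=None,
                     exclude_sections=("References",),
                     directional_trigger_extension: bool = True
                     ) -> list[ImpactRelation]:
    """Extract all typed impact relations from one document.

    Per-sentence pipeline: segment -> parse -> triggers -> patterns ->
    ground -> type. Document-local abbreviation aliases are collected
    first so short forms ground anywhere in the document. A provider
    failure on a sentence is logged and skipped, not raised. Output is
    deterministic: document order, then span order.
    """
    if provider is None:
        provider = ShallowParseProvider()
    if trigger_lexicon is None or cues is None:
        from . import defaults
        trigger_lexicon = trigger_lexicon or defaults.default_triggers()
        cues = cues or defaults.default_cues()
    sentences = segment_sentences(doc)
    if include_sections is not None:
        sentences = [s for s in sentences if s.section_title in include_sections]
    if exclude_sections:
        sentences = [s for s in sentences
                     if s.section_title not in exclude_sections]
    collect_document_aliases(lex, doc.doc_id, sentences)
    out: list[ImpactRelation] = []
    for sent in sentences:
        try:
            out.extend(
                extract_sentence(sent, lex, provider, trigger_lexicon, cues,
                                 directional_trigger_extension)
            )
        except Exception:  # noqa: BLE001 - a bad sentence must not kill a run
            logger.exception("extraction failed on %s; skipping", sent.sent_id)
    return out


def extract_corpus(docs: Iterable[SourceDocument], lex: Lexicon, **kwargs
                   ) -> list[ImpactRelation]:
    out: list[ImpactRelation] = []
    for doc in docs:
        out.extend(extract_document(doc, lex, **kwargs))
    return out


# ---------------------------------------------------------------------------
# relation JSON-Lines round trip

def relations_to_jsonl(relations: Iterable[ImpactRelation], fh: IO[str]
                       ) -> None:
    for r in relations:
        fh.write(json.dumps(r.to_record(), ensure_ascii=False) + "\n")


def relations_from_jsonl(fh: IO[str], lex: Lexicon) -> list[ImpactRelation]:
    """Rebuild relations from their JSON-Lines records (for build-kg)."""
    out: list[ImpactRelation] = []
    for idx, line in enumerate(fh):
        if not line.strip():
            continue
        rec = json.loads(line)
        sent = Sentence(
            sent_id=f"{rec['doc_id']}:jsonl:{idx}",
            text=rec["sentence"],
            section_title=rec["section_title"],
            doc_id=rec["doc_id"],
            doc_kind=rec["doc_kind"],
            chapter_number=rec.get("chapter_number"),
            start=0,
            end=len(rec["sentence"]),
        )
        aff = ConceptMatch(
            concept=lex.concepts[rec["affector_coid"]],
            matched_text=rec["affector_term"],
            span=(0, len(rec["affector_term"])),
        )
        afd = ConceptMatch(
            concept=lex.concepts[rec["affected_coid"]],
            matched_text=rec["affected_term"],
            span=(0, len(rec["affected_term"])),
        )
        out.append(
            ImpactRelation(
                affector=aff,
                affected=afd,
                trigger=rec["trigger"],
                relation_type=rec["relation_type"],
                pattern_id=rec.get("pattern_id", "P1_simple"),
                sentence=sent,
            )
        )
    return out
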