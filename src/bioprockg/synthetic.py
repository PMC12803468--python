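"""Seeded synthetic corpus generator with gold relations by construction.

Generates abstract-like documents whose non-distractor sentences each
instantiate exactly one of the five pattern families with two sampled
dictionary concepts, a category-appropriate trigger and optional cue
words; the gold relation type of each sentence is computed from its own
components through the cue classifier, so extraction closure (precision
= recall = 1 on in-scope templates) is checkable end to end. Distractor
sentences reuse bioprocess-sounding vocabulary absent from the
dictionary to exercise the relevance filter.

Templates use deliberately simple clause structure — the generator's job
is stage testing, not linguistic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .documents import GoldAnnotation, SourceDocument
from .errors import ConfigurationError
from .lexicon import Lexicon
from .reltype import CueLexicon, classify, scan_cues

PATTERNS = ("P1", "P2", "P3", "P4", "P5")

_POS_ADJ = ("elevated", "increased", "enhanced")
_NEG_ADJ = ("reduced", "decreased", "impaired")

_P1_TRIGGERS = ("affects", "regulates", "modulates", "controls",
                "increases", "reduces", "enhances", "inhibits")
_P1_BASES = {"affects": "affect", "regulates": "regulate",
             "modulates": "modulate", "controls": "control",
             "increases": "increase", "reduces": "reduce",
             "enhances": "enhance", "inhibits": "inhibit"}
_P2_FORMS = ("was caused by", "was enabled by", "resulted from")
_P3_NOUNS = ("impact", "effect", "influence")
_P4_FORMS = ("is associated with", "correlates with", "is linked to")
_P4_ADVERBS = (None, "positively", "negatively")
_P5_ADJ = ("higher", "lower", "greater")

_DISTRACTORS = (
    "The impeller speed affects foam formation in stirred tanks.",
    "Sparging rate increases shear stress near the probe assembly.",
    "Filter clogging was caused by harvest turbidity.",
    "Sensor drift is associated with valve timing offsets.",
    "Column fouling reduces buffer throughput during polishing.",
    "Samples were stored frozen until further analysis.",
    "The effect of antifoam dosage on sensor drift was investigated.",
)

_TAILS = ("in fed-batch cultures", "under standard conditions",
          "in stirred-tank bioreactors", "during the production phase")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    n_documents: int = 40
    seed: int = 0
    pattern_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    cue_mix: tuple[float, float, float] = (0.35, 0.25, 0.10)
    distractor_rate: float = 0.3
    sentences_per_doc: int = 6

    def __post_init__(self):
        if self.n_documents <= 0 or self.sentences_per_doc <= 0:
            raise ConfigurationError("corpus dimensions must be positive")
        if not (0 <= self.distractor_rate <= 1):
            raise ConfigurationError("distractor_rate must be in [0, 1]")
        if len(self.pattern_mix) != 5 or min(self.pattern_mix) < 0 or \
                sum(self.pattern_mix) <= 0:
            raise ConfigurationError("pattern_mix needs 5 non-negative weights")
        p_pos, p_neg, p_negation = self.cue_mix
        if min(self.cue_mix) < 0 or p_pos + p_neg > 1 or p_negation > 1:
            raise ConfigurationError("cue_mix probabilities out of range")


def _sentence_case(s: str) -> str:
    return s[0].upper() + s[1:] if s and s[0].islower() else s


def generate_corpus(cfg: GeneratorConfig, lex: Lexicon,
                    cues: CueLexicon | None = None
                    ) -> tuple[list[SourceDocument], list[GoldAnnotation]]:
    """Generate (documents, gold annotations) for the given config.

    Identical (cfg, lexicon) input reproduces identical output. Raises
    :class:`ConfigurationError` when the lexicon has fewer than two
    concepts.
    """
    if cues is None:
        from . import defaults
        cues = defaults.default_cues()
    concepts = sorted(lex.concepts.values(), key=lambda c: c.coid)
    if len(concepts) < 2:
        raise ConfigurationError(
            "synthetic corpus needs a lexicon with at least 2 concepts"
        )
    rng = np.random.default_rng(cfg.seed)
    weights = np.asarray(cfg.pattern_mix, dtype=float)
    weights = weights / weights.sum()
    p_pos, p_neg, p_negation = cfg.cue_mix

    docs: list[SourceDocument] = []
    golds: list[GoldAnnotation] = []
    for d in range(cfg.n_documents):
        doc_id = str(90000000 + d)
        sentences: list[str] = []
        for _ in range(cfg.sentences_per_doc):
            if rng.random() < cfg.distractor_rate:
                sentences.append(
                    _DISTRACTORS[rng.integers(len(_DISTRACTORS))]
                )
                continue
            pattern = PATTERNS[rng.choice(5, p=weights)]
            i, j = rng.choice(len(concepts), size=2, replace=False)
            aff = concepts[i].canonical_name
            afd = concepts[j].canonical_name
            text, gold_type = _render(pattern, aff, afd, rng,
                                      (p_pos, p_neg, p_negation), cues)
            sentences.append(text)
            golds.append(
                GoldAnnotation(
                    doc_id=doc_id,
                    affector_term=aff,
                    affected_term=afd,
                    relation_type=gold_type,
                    sentence_text=text,
                )
            )
        docs.append(
            SourceDocument(
                doc_id=doc_id,
                doc_kind="abstract",
                sections=(("Abstract", " ".join(sentences)),),
            )
        )
    return docs, golds


def _cue_adj(rng, p_pos, p_neg) -> str | None:
    r = rng.random()
    if r < p_pos:
        return _POS_ADJ[rng.integers(len(_POS_ADJ))]
    if r < p_pos + p_neg:
        return _NEG_ADJ[rng.integers(len(_NEG_ADJ))]
    return None


def _np(name: str, adj: str | None) -> str:
    return f"{adj} {name}" if adj else name


def _render(pattern: str, aff: str, afd: str, rng, cue_probs, cues
            ) -> tuple[str, str]:
    """Render one sentence; gold type follows from its own cue words."""
    p_pos, p_neg, p_negation = cue_probs
    adj_a = _cue_adj(rng, p_pos, p_neg)
    adj_b = _cue_adj(rng, p_pos, p_neg)
    aff_np = _np(aff, adj_a)
    afd_np = _np(afd, adj_b)
    tail = _TAILS[rng.integers(len(_TAILS))]
    negated = False
    trig_context = ""

    if pattern == "P1":
        trig = _P1_TRIGGERS[rng.integers(len(_P1_TRIGGERS))]
        lemma = _P1_BASES[trig]
        if rng.random() < p_negation:
            negated = True
            text = f"{_sentence_case(aff_np)} does not {lemma} {afd_np} {tail}."
        else:
            text = f"{_sentence_case(aff_np)} {trig} {afd_np} {tail}."
    elif pattern == "P2":
        form = _P2_FORMS[rng.integers(len(_P2_FORMS))]
        lemma = {"was caused by": "cause", "was enabled by": "enable",
                 "resulted from": "result"}[form]
        text = f"{_sentence_case(afd_np)} {form} {aff_np} {tail}."
    elif pattern == "P3":
        noun = _P3_NOUNS[rng.integers(len(_P3_NOUNS))]
        lemma = noun
        if rng.random() < p_negation:
            negated = True
            text = f"No {noun} of {aff_np} on {afd_np} was observed."
        else:
            text = f"The {noun} of {aff_np} on {afd_np} was investigated."
    elif pattern == "P4":
        form = _P4_FORMS[rng.integers(len(_P4_FORMS))]
        lemma = {"is associated with": "associate",
                 "correlates with": "correlate",
                 "is linked to": "link"}[form]
        adverb = _P4_ADVERBS[rng.integers(len(_P4_ADVERBS))]
        if adverb:
            verb, particle = form.rsplit(" ", 1)
            form = f"{verb} {adverb} {particle}"
            trig_context = adverb
        text = f"{_sentence_case(aff_np)} {form} {afd_np} {tail}."
    else:  # P5 — comparison always carries a comparative on the aspect
        adj_b = _P5_ADJ[rng.integers(len(_P5_ADJ))]
        afd_np = f"{adj_b} {afd} levels"
        lemma = "than"
        text = (f"{_sentence_case(aff_np)} cultures had {afd_np} "
                f"than control cultures.")
        aff_np = f"{aff_np} cultures"

    flags = scan_cues(aff_np, afd_np, lemma, trigger_context=trig_context,
                      cues=cues, trigger_negated=negated)
    return text, classify(flags)
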