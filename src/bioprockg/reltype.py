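"""Four-way correlation typing from lexical cues.

Each candidate relation is typed by scanning three components — the
affector noun phrase, the affected noun phrase and the trigger (with its
immediate context) — for positive and negative cue words, plus a
negation check directly before the trigger. The decision is evaluated in
strict precedence:

1. negated trigger                          -> not_correlated
2. any negative cue                         -> negatively_correlated
3. positive cues in at least two components -> positively_correlated
4. a directional positive trigger alone     -> positively_correlated
5. otherwise                                -> correlated_not_specified

Rule 4 mirrors the lone-negative-trigger logic of rule 2 ("reduces"
between two neutral phrases is negative): "enhances" between two neutral
phrases is positive. It can be switched off.

Note the literal precedence makes double-negative phrasings ("reduced X
leads to reduced Y") negatively_correlated even though sign-product
semantics would call them positive; the cue heuristic is implemented as
stated, not as an algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import yaml

from .errors import ConfigurationError
from .textnorm import match_lemma, normalize, tokenize

RELATION_TYPES = (
    "positively_correlated",
    "negatively_correlated",
    "not_correlated",
    "correlated_not_specified",
)


@dataclass(frozen=True)
class CueLexicon:
    """Disjoint positive / negative / negation cue lemma sets."""

    positive: frozenset[str]
    negative: frozenset[str]
    negation: frozenset[str]

    def __post_init__(self):
        overlap = (
            (self.positive & self.negative)
            | (self.positive & self.negation)
            | (self.negative & self.negation)
        )
        if overlap:
            raise ConfigurationError(
                f"cue sets must be pairwise disjoint; shared: {sorted(overlap)}"
            )


def load_cues(source: str | IO) -> CueLexicon:
    """Load the cue lexicon from a YAML mapping with keys
    ``positive``, ``negative``, ``negation``."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    try:
        return CueLexicon(
            positive=frozenset(data["positive"]),
            negative=frozenset(data["negative"]),
            negation=frozenset(data["negation"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"cue lexicon missing key {exc}") from exc


@dataclass(frozen=True)
class ComponentCues:
    """Cue flags per component, derived solely from cue-lexicon hits."""

    affector_pos: bool = False
    affector_neg: bool = False
    affected_pos: bool = False
    affected_neg: bool = False
    trigger_pos: bool = False
    trigger_neg: bool = False
    trigger_negated: bool = False


def _has_cue(text: str, cue_set: frozenset[str]) -> bool:
    if not text:
        return False
    norm = normalize(text)
    low = norm.lower()
    # hyphenated multi-token cues ("up-regulated") are checked on the string
    for cue in cue_set:
        if "-" in cue and cue in low:
            return True
    for tok in tokenize(norm):
        if tok.text.isalpha() and match_lemma(tok.text, cue_set):
            return True
    return False


def scan_cues(
    affector_text: str,
    affected_text: str,
    trigger_lemma: str,
    trigger_context: str = "",
    cues: CueLexicon | None = None,
    trigger_negated: bool | None = None,
) -> ComponentCues:
    """Scan the two argument phrases and the trigger for cue words.

    ``trigger_context`` holds the tokens adjacent to the trigger (so
    "correlates positively with" contributes a positive trigger cue).
    ``trigger_negated`` may be passed explicitly (the extractor computes
    it from the token window before the trigger); if None it is derived
    from negation cues in the context.
    """
    if cues is None:
        raise ConfigurationError("a CueLexicon is required")
    trig_text = f"{trigger_lemma} {trigger_context}".strip()
    if trigger_negated is None:
        trigger_negated = _has_cue(trigger_context, cues.negation)
    return ComponentCues(
        affector_pos=_has_cue(affector_text, cues.positive),
        affector_neg=_has_cue(affector_text, cues.negative),
        affected_pos=_has_cue(affected_text, cues.positive),
        affected_neg=_has_cue(affected_text, cues.negative),
        trigger_pos=_has_cue(trig_text, cues.positive),
        trigger_neg=_has_cue(trig_text, cues.negative),
        trigger_negated=bool(trigger_negated),
    )


def classify(c: ComponentCues, directional_trigger_extension: bool = True
             ) -> str:
    """Assign one of the four correlation types to a cue configuration."""
    if c.trigger_negated:
        return "not_correlated"
    if c.affector_neg or c.affected_neg or c.trigger_neg:
        return "negatively_correlated"
    n_pos = sum((c.affector_pos, c.affected_pos, c.trigger_pos))
    if n_pos >= 2:
        return "positively_correlated"
    if directional_trigger_extension and c.trigger_pos:
        return "positively_correlated"
    return "correlated_not_specified"
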