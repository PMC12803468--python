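"""Parse-provider contract and the shallow, dependency-free provider.

The extraction rules are written against a small contract — tokens with
offsets, an appositive mask, and word-class predicates — so a full
dependency parser can be plugged in, while the bundled shallow provider
needs no model download: it chunks noun phrases by scanning outward from
trigger words over closed word lists (auxiliaries, adverbs, clause
connectives). Output is deterministic for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from .textnorm import Token, normalize, tokenize

AUX = {
    "is", "are", "was", "were", "be", "been", "being", "am",
    "has", "have", "had", "do", "does", "did",
    "can", "could", "may", "might", "must", "shall", "should",
    "will", "would",
}

#: words that, after a comma (or "and"/"or" + auxiliary), start a new clause
CONNECTIVES = {
    "thereby", "although", "though", "despite", "whereas", "while",
    "suggesting", "indicating", "resulting", "which", "who", "but",
    "however", "because", "since", "yet", "moreover", "furthermore",
    "likewise", "when", "where",
}

PRONOUNS = {"we", "they", "it", "he", "she", "i", "this", "these", "those",
            "there"}

RELATIVE = {"that", "which", "who"}

_EXTRA_ADVERBS = {"most", "also", "often", "further", "well", "already"}


def is_adverb(word: str) -> bool:
    w = word.lower()
    return (w.endswith("ly") and len(w) > 3) or w in _EXTRA_ADVERBS


@dataclass(frozen=True)
class ParsedSentence:
    """Tokenized sentence plus the appositive mask.

    ``masked`` holds indices of tokens inside non-restrictive appositive
    clauses (", which refers to ...,"), which are skipped when locating
    argument noun phrases. ``full_parse`` is False for the shallow
    provider (no dependency edges / POS tags are available).
    """

    text: str
    tokens: tuple[Token, ...]
    masked: frozenset[int] = frozenset()
    provider: str = "shallow"
    full_parse: bool = False

    def span_text(self, start_tok: int, end_tok: int) -> str:
        """Sentence substring covering tokens [start_tok, end_tok]."""
        return self.text[self.tokens[start_tok].start: self.tokens[end_tok].end]


class ParseProvider(Protocol):
    name: str
    full_parse: bool

    def parse(self, text: str) -> ParsedSentence: ...


_APPOSITIVE_STARTERS = {"which", "who"}


def _appositive_mask(tokens: tuple[Token, ...]) -> frozenset[int]:
    """Mask ", which ... ," style non-restrictive clauses.

    Only comma-introduced relatives are masked; bare "X which was caused
    by Y" relatives stay visible because they carry arguments.
    """
    masked: set[int] = set()
    i = 0
    n = len(tokens)
    while i < n - 1:
        if tokens[i].text == "," and tokens[i + 1].low in _APPOSITIVE_STARTERS:
            j = i + 2
            while j < n and tokens[j].text != ",":
                j += 1
            if j < n:  # only mask if the clause closes with a comma
                masked.update(range(i, j + 1))
                i = j + 1
                continue
        i += 1
    return frozenset(masked)


class ShallowParseProvider:
    """Pattern-mode provider: tokenization + appositive masking only."""

    name = "shallow"
    full_parse = False

    def parse(self, text: str) -> ParsedSentence:
        norm = normalize(text)
        tokens = tuple(tokenize(norm))
        return ParsedSentence(
            text=norm,
            tokens=tokens,
            masked=_appositive_mask(tokens),
            provider=self.name,
            full_parse=False,
        )
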