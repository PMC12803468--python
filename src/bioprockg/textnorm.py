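"""Text normalization, tokenization and sentence splitting.

All downstream matching (dictionary grounding, trigger detection, cue
scanning) happens on NFC-normalized text where sub/superscript digits are
mapped to ASCII ("CO₂" -> "CO2") and typographic dashes/quotes are
folded, because the dictionary stores ASCII surface forms.  Offsets are
0-based, half-open, character indexed.
"""

from __future__ import annotations

import re
import unicodedata
from typing import NamedTuple

_SUBSUP = {
    "₀": "0", "₁": "1", "₂": "2", "₃": "3",
    "₄": "4", "₅": "5", "₆": "6", "₇": "7",
    "₈": "8", "₉": "9",
    "⁰": "0", "¹": "1", "²": "2", "³": "3",
    "⁴": "4", "⁵": "5", "⁶": "6", "⁷": "7",
    "⁸": "8", "⁹": "9",
    "−": "-", "–": "-", "—": "-",  # minus, en/em dash
    "‘": "'", "’": "'", "“": '"', "”": '"',
    " ": " ",
}
_SUBSUP_TABLE = str.maketrans(_SUBSUP)


def normalize(text: str) -> str:
    """NFC-normalize and fold sub/superscripts and dashes to ASCII."""
    return unicodedata.normalize("NFC", text).translate(_SUBSUP_TABLE)


class Token(NamedTuple):
    text: str
    start: int
    end: int

    @property
    def low(self) -> str:
        return self.text.lower()


_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[Token]:
    """Whitespace/punctuation tokenizer with character offsets.

    Hyphens and other punctuation become their own tokens, so hyphens act
    as word boundaries ("MnCl" never contains a token "Mn").
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


_IRREGULAR = {
    "shown": "show", "showed": "show",
    "led": "lead",
    "given": "give", "gave": "give",
    "arose": "arise", "arisen": "arise",
}


def lemma_candidates(word: str) -> list[str]:
    """Candidate lemmas for an inflected English word (suffix stripping).

    Deliberately over-generates; callers intersect with a closed lexicon,
    so spurious candidates are harmless.
    """
    w = word.lower()
    out = [w]
    if w in _IRREGULAR:
        out.append(_IRREGULAR[w])
    n = len(w)
    if w.endswith("ies") and n > 4:
        out.append(w[:-3] + "y")
    if w.endswith("s") and not w.endswith("ss") and n > 3:
        out.append(w[:-1])
    if w.endswith("es") and n > 4:
        out.append(w[:-2])
    if w.endswith("ed") and n > 4:
        out.append(w[:-1])   # caused -> cause
        out.append(w[:-2])   # impacted -> impact
        if n > 5 and w[-3] == w[-4]:
            out.append(w[:-3])  # controlled -> control
    if w.endswith("ing") and n > 5:
        stem = w[:-3]
        out.append(stem)          # affecting -> affect
        out.append(stem + "e")    # increasing -> increase
        if len(stem) > 2 and stem[-1] == stem[-2]:
            out.append(stem[:-1])  # controlling -> control
    return out


def match_lemma(word: str, lemmas) -> str | None:
    """First candidate lemma of *word* contained in *lemmas*, else None."""
    for cand in lemma_candidates(word):
        if cand in lemmas:
            return cand
    return None


# Tokens (sans trailing period) after which a period never ends a sentence.
_ABBREVS = {
    "al", "et", "fig", "figs", "eq", "eqs", "ref", "refs", "e.g", "i.e",
    "vs", "ca", "approx", "cf", "resp", "dr", "prof", "st", "no", "etc",
    "sp", "spp", "var", "min", "max",
}

_CLOSERS = '"\')]'


def split_sentence_spans(text: str) -> list[tuple[int, int]]:
    """Sentence boundaries as (start, end) spans into *text*.

    Rule-based: a sentence ends at ``. ! ?`` followed by whitespace and an
    uppercase letter or digit, never inside parentheses/brackets and never
    after a known abbreviation ("et al.", "Fig.", initials).
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    depth = 0
    start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif ch in ".!?" and depth == 0:
            j = i + 1
            while j < n and text[j] in _CLOSERS:
                j += 1
            if j >= n:
                i += 1
                continue
            if not text[j].isspace():
                i += 1
                continue
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k < n and not (text[k].isupper() or text[k].isdigit()):
                i += 1
                continue
            if ch == ".":
                m = re.search(r"([\w.]+)$", text[:i])
                prev = m.group(1).lower().rstrip(".") if m else ""
                if prev in _ABBREVS or (len(prev) == 1 and prev.isalpha()):
                    i += 1
                    continue
            spans.append((start, j))
            start = k
            i = k
            continue
        i += 1
    if start < n:
        spans.append((start, n))
    # trim whitespace inside each span
    trimmed = []
    for a, b in spans:
        while a < b and text[a].isspace():
            a += 1
        while b > a and text[b - 1].isspace():
            b -= 1
        if b > a:
            trimmed.append((a, b))
    return trimmed
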