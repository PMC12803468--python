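"""Dictionary concepts and surface-form grounding.

A dictionary concept aggregates every textual variant of one domain term
(synonyms, abbreviations, spellings) under a single COID-identified
canonical name, typed by an ontology class. Grounding maps free text to
concepts with longest, token-boundary-aligned, non-overlapping matches;
document-local abbreviation pairs (Schwartz–Hearst style) extend the
global index without polluting it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

from .errors import AmbiguityError, FormatError
from .textnorm import normalize

_COID_RE = re.compile(r"^COID\d{6}$")
_WORDCHARS = "A-Za-z0-9"


@dataclass(frozen=True)
class DictionaryConcept:
    """A canonical concept with alternative surface forms and a TYPE."""

    coid: str
    canonical_name: str
    alt_names: frozenset[str] = frozenset()
    type_id: str = ""
    type_name: str = ""

    def __post_init__(self):
        if not _COID_RE.match(self.coid):
            raise FormatError(
                f"malformed concept id {self.coid!r} (expected COID + 6 digits)"
            )

    @property
    def surface_forms(self) -> frozenset[str]:
        return self.alt_names | {self.canonical_name}


@dataclass(frozen=True)
class ConceptMatch:
    """A dictionary hit inside a phrase; span is 0-based half-open."""

    concept: DictionaryConcept
    matched_text: str
    span: tuple[int, int]


@dataclass(frozen=True)
class AbbreviationPair:
    """A (short form, long form) pair detected from a parenthesis."""

    short_form: str
    long_form: str
    sent_id: str | None = None


def _surface_pattern(surface: str) -> re.Pattern:
    """Compile a token-boundary-aligned pattern for one surface form.

    Matching is case-insensitive except for all-uppercase short forms
    (e.g. "ADCC", "DO"), which must match exactly — lowercase "do" must
    not hit the dissolved-oxygen abbreviation.
    """
    body = re.escape(surface)
    pat = rf"(?<![{_WORDCHARS}]){body}(?![{_WORDCHARS}])"
    flags = 0 if _is_cased_short_form(surface) else re.IGNORECASE
    return re.compile(pat, flags)


def _is_cased_short_form(surface: str) -> bool:
    letters = [c for c in surface if c.isalpha()]
    return bool(letters) and all(c.isupper() for c in letters)


class Lexicon:
    """Concept dictionary plus (optional) per-document abbreviation aliases."""

    def __init__(self, concepts: Iterable[DictionaryConcept] = ()):
        self.concepts: dict[str, DictionaryConcept] = {}
        self._index: dict[str, DictionaryConcept] = {}  # normalized key -> concept
        self._patterns: list[tuple[re.Pattern, DictionaryConcept, int]] = []
        self.doc_aliases: dict[str, dict[str, DictionaryConcept]] = {}
        for c in concepts:
            self.add_concept(c)

    def __len__(self) -> int:
        return len(self.concepts)

    def add_concept(self, concept: DictionaryConcept) -> None:
        if concept.coid in self.concepts:
            raise AmbiguityError(f"duplicate COID {concept.coid}")
        for surface in sorted(concept.surface_forms):
            key = self._key(surface)
            prior = self._index.get(key)
            if prior is not None and prior.coid != concept.coid:
                raise AmbiguityError(
                    f"surface form {surface!r} is ambiguous between "
                    f"{prior.coid} and {concept.coid}"
                )
            self._index[key] = concept
            self._patterns.append((_surface_pattern(normalize(surface)), concept, 0))
        self.concepts[concept.coid] = concept

    @staticmethod
    def _key(surface: str) -> str:
        s = normalize(surface)
        return s if _is_cased_short_form(s) else s.casefold()

    # -- document-scoped aliases -------------------------------------------
    def add_doc_alias(self, doc_id: str, short_form: str,
                      concept: DictionaryConcept) -> None:
        key = self._key(short_form)
        if key in self._index:
            return  # already globally known
        self.doc_aliases.setdefault(doc_id, {})[key] = concept

    def _doc_patterns(self, doc_id: str):
        for key, concept in self.doc_aliases.get(doc_id, {}).items():
            yield _surface_pattern(key), concept, 1

    # -- lookup -------------------------------------------------------------
    def lookup(self, surface: str, doc_id: str | None = None
               ) -> DictionaryConcept | None:
        key = self._key(surface)
        hit = self._index.get(key)
        if hit is None and doc_id is not None:
            hit = self.doc_aliases.get(doc_id, {}).get(key)
        return hit

    def to_json(self) -> str:
        rows = [
            {
                "coid": c.coid,
                "canonical_name": c.canonical_name,
                "alt_names": sorted(c.alt_names),
                "type_id": c.type_id,
                "type_name": c.type_name,
            }
            for c in sorted(self.concepts.values(), key=lambda c: c.coid)
        ]
        return json.dumps(rows, indent=2, ensure_ascii=False)


def load_dictionary(source: str | IO | pd.DataFrame) -> Lexicon:
    """Load a concept table (TSV with pipe-separated alt_names).

    Columns: ``coid``, ``canonical_name``, ``alt_names``, ``type_id``,
    ``type_name``. Surface-form collisions across concepts raise
    :class:`AmbiguityError`; malformed COIDs raise :class:`FormatError`.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = {"coid", "canonical_name", "alt_names", "type_id", "type_name"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"dictionary table missing columns: {sorted(missing)}")
    lex = Lexicon()
    for row in df.itertuples(index=False):
        alts = frozenset(a.strip() for a in row.alt_names.split("|") if a.strip())
        lex.add_concept(
            DictionaryConcept(
                coid=row.coid.strip(),
                canonical_name=row.canonical_name.strip(),
                alt_names=alts,
                type_id=row.type_id.strip(),
                type_name=row.type_name.strip(),
            )
        )
    return lex


# ---------------------------------------------------------------------------
# abbreviation detection (Schwartz & Hearst-style short/long form alignment)

_PAREN_RE = re.compile(r"\(([^()]{1,40})\)")
_STOP_FIRST = {"the", "a", "an", "of", "in", "at", "on", "and", "or", "by"}


def detect_abbreviations(sentence, sent_id: str | None = None
                         ) -> list[AbbreviationPair]:
    """Detect ``long form (SF)`` abbreviation pairs in one sentence.

    A candidate short form must start with a letter, span at most two
    words, and every alphanumeric character must appear, in order, in the
    long form, with the first letter anchored at a word start. Numeric
    short forms like "(3 L)" are rejected.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    if sent_id is None and not isinstance(sentence, str):
        sent_id = sentence.sent_id
    text = normalize(text)
    pairs: list[AbbreviationPair] = []
    for m in _PAREN_RE.finditer(text):
        sf = m.group(1).strip()
        if not sf or "," in sf or len(sf) > 12 or len(sf.split()) > 2:
            continue
        if not sf[0].isalpha():
            continue
        if not any(c.isalpha() for c in sf):
            continue
        if sf.split()[0].lower() in _STOP_FIRST:
            continue
        before = text[: m.start()].rstrip()
        lf = _best_long_form(sf, before)
        if lf:
            pairs.append(AbbreviationPair(short_form=sf, long_form=lf,
                                          sent_id=sent_id))
    return pairs


def _best_long_form(sf: str, before: str) -> str | None:
    chars = [c.lower() for c in sf if c.isalnum()]
    if not chars:
        return None
    words = before.split()
    max_words = min(len(chars) + 5, len(chars) * 2, len(words))
    if max_words == 0:
        return None
    candidate_words = words[-max_words:]
    cand = " ".join(candidate_words)
    # right-to-left alignment (Schwartz & Hearst)
    li = len(cand) - 1
    for ci in range(len(chars) - 1, -1, -1):
        c = chars[ci]
        while li >= 0:
            at_word_start = li == 0 or not cand[li - 1].isalnum()
            if cand[li].lower() == c and (ci > 0 or at_word_start):
                break
            li -= 1
        if li < 0:
            return None
        li -= 1
    # the long form starts at the word containing the first-character match
    start = li + 1
    while start > 0 and cand[start - 1] != " ":
        start -= 1
    lf = cand[start:].strip()
    if not lf or len(lf.split()) > len(chars) + 4:
        return None
    if lf.lower() == sf.lower():
        return None
    return lf


# ---------------------------------------------------------------------------
# grounding

def ground_phrase(lex: Lexicon, phrase: str, doc_id: str | None = None
                  ) -> list[ConceptMatch]:
    """Ground a phrase to dictionary concepts.

    Returns longest, non-overlapping, token-boundary-aligned matches,
    ordered by span start. Document-local abbreviation aliases are
    consulted after the global index (global hits win on overlap).
    """
    if not phrase:
        return []
    norm = normalize(phrase)
    candidates: list[tuple[int, int, int, DictionaryConcept]] = []
    pattern_sources = list(lex._patterns)
    if doc_id is not None:
        pattern_sources.extend(lex._doc_patterns(doc_id))
    for pat, concept, rank in pattern_sources:
        for m in pat.finditer(norm):
            candidates.append((m.start(), m.end(), rank, concept))
    # longest match wins; among equal lengths, leftmost; global before alias
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    chosen: list[tuple[int, int, DictionaryConcept]] = []
    for start, end, _rank, concept in candidates:
        if any(s < end and start < e for s, e, _ in chosen):
            continue
        chosen.append((start, end, concept))
    chosen.sort(key=lambda t: t[0])
    return [
        ConceptMatch(concept=c, matched_text=norm[s:e], span=(s, e))
        for s, e, c in chosen
    ]


def collect_document_aliases(lex: Lexicon, doc_id: str, sentences) -> None:
    """Scan sentences for abbreviation pairs and register document aliases.

    An alias is added only when the long form itself grounds to a concept,
    mirroring the use of the abbreviation detector for term
    standardization without polluting the global index.
    """
    for s in sentences:
        for pair in detect_abbreviations(s):
            matches = ground_phrase(lex, pair.long_form)
            if len(matches) == 1:
                lex.add_doc_alias(doc_id, pair.short_form, matches[0].concept)
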