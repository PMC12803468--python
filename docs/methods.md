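# Methods

This note records the modelling choices behind `bioprockg`: what the
pipeline assumes, which knobs matter, what the synthetic corpus does
and does not demonstrate, and where the design was genuinely open.

## Scope and assumptions

The system extracts sentence-level impact claims between
biopharmaceutical process parameters (pH, osmolality, pCO2, trace
metals, media composition, ...) and product/biological outcomes
(glycoform levels such as galactosylation or afucosylation, ADCC,
productivity, apoptosis, ...). Assumptions baked in:

- **One sentence, one context.** Relations never span sentences; there
  is no co-reference resolution. A claim like "this effect was
  reversed at higher pH" in a following sentence is out of reach.
- **Relevance via the dictionary.** An argument noun phrase only
  survives if part of it is a lexicalization of a dictionary concept.
  The dictionary therefore doubles as the relevance filter: extraction
  quality is bounded by dictionary coverage.
- **Stored, not adjudicated.** Contradictory claims from different
  sources become parallel edges with their own provenance; the graph
  performs no conflict resolution and asserts no causality.

## The parse-provider contract and the shallow provider

Extraction rules are written against a small contract (tokens with
character offsets, an appositive mask, closed word classes), so a full
dependency parser can be plugged in. The bundled provider is a shallow
pattern matcher: it tokenizes, masks non-restrictive appositives
(", which ...,"), and locates argument spans by scanning outward from
trigger tokens to clause boundaries (other triggers and their
particles, colons/semicolons, commas followed by connectives or
pronouns, auxiliaries, relative markers, comparison markers). Three
disambiguation rules carry most of the weight:

- **Attributive vs. verbal participles.** Directional verbs double as
  cue adjectives ("an *increased* apoptosis rate" vs. "uridine
  *increased* galactosylation"). An `-ed` form of a directional trigger
  is treated as attributive — a cue inside the NP, not a trigger —
  when preceded by a determiner, preposition, conjunction, relative
  marker, or another trigger; it stays verbal after an auxiliary
  (passives: "was reduced by") or a noun/comma (finite past).
- **Relative-clause hop.** When the leftward scan for a subject hits a
  trigger headed by "that/which" ("conditions **that inhibit** X ...
  and consequently **lead to** Y"), the relative clause's material is
  discarded and the scan resumes with the outer subject NP.
- **Generic-head elaboration.** Subjects like "three process
  parameters" or "compounds" name their referents in a trailing colon
  list or a parenthesized list; when such a generic-headed NP has no
  dictionary hit, the list text stands in for it.

Unicode is NFC-normalized with sub/superscript digits folded to ASCII
before any matching, because dictionary surface forms are stored in
ASCII. Offsets are 0-based, half-open, character-indexed. All provider
output is deterministic.

## Tunable resources (units: word lists)

- **Trigger lexicon** (`resources/triggers.yaml`): lemmas per category
  *impact / causal / regulation / association / comparison*. The
  shipped inventory covers the canonical verbs plus directional verbs
  (increase, reduce, enhance, inhibit, ...) and the weak association
  verbs *show*/*exhibit*; it is configuration, not code — domain teams
  are expected to extend it.
- **Cue lexicon** (`resources/cues.yaml`): disjoint positive /
  negative / negation lemma sets, scanned lemma-level in the two
  argument phrases and the trigger context. Noun forms (reduction,
  loss, lack) are listed alongside verbs because scanning is not
  POS-aware. *influence* sits in the positive set: "parameters that
  influence afucosylation" reads as a positive impact claim, unlike
  the genuinely neutral *impact*/*affect*/*effect*.
- **Negation window**: a negation token within 3 tokens before the
  trigger, with no intervening punctuation, negates it. The
  punctuation bound prevents "with or without uridine, increased X"
  from being read as negated.
- **Dictionary / ontology**: TSV tables (30 concepts / 22 classes
  bundled as a working fixture set centred on CHO glycosylation).
  Matching is case-insensitive except all-uppercase short forms
  (ADCC, VCD), which must match exactly; hyphens count as token
  boundaries; longest match wins, leftmost on ties.

## Typing precedence

`not_correlated` (negated trigger) ≻ `negatively_correlated` (any
negative cue) ≻ `positively_correlated` (positive cues in ≥ 2
components, or a lone directionally positive trigger) ≻
`correlated_not_specified`. Two deliberate readings:

- A lone positive *trigger* suffices for a positive label (mirroring
  the lone-negative-trigger case, "reduces"), but a lone positive cue
  in one argument does not; the extension is a flag
  (`directional_trigger_extension`) defaulting on.
- Double negatives ("reduced X leads to reduced Y") type as
  negatively_correlated, as the precedence rules state — no
  sign-product algebra is attempted.

## Knowledge graph and queries

Term nodes are deduplicated per surface form (not per mention), with
separate Affector and Affected node spaces; impact edges merge
provenance per (affector term, affected term, type). Path joins are
concept-level through HAS_CONCEPT, so "afucosylation" mentioned in one
article chains with "afucosylation" in another regardless of surface
form. Only `is_a` edges expand class membership in class-level queries;
`role`/`catalyst`/`result` edges are stored and exportable but not
traversed — non-taxonomic traversal would inflate memberships. Queries
return simple paths only (no repeated concepts) with a degree of
separation capped at 5; results are ordered by length then concept
names. Wildcard patterns are case-insensitive substrings with `*`.
All four relation types participate by default; restricting to a
subset (e.g. excluding `not_correlated` from transitive chains) is the
caller's choice via `rel_types`.

## Synthetic corpus: what it shows and what it does not

The generator emits abstracts whose non-distractor sentences each
instantiate exactly one pattern family with two sampled dictionary
concepts, a category-appropriate trigger, and cue words whose
configuration determines the gold type through the same precedence
rules (label consistency is a tested invariant). Defaults: 40
documents × 6 sentences, equal pattern weights, cue probabilities
0.35/0.25/0.10 (positive/negative/negation), 30 % distractor sentences
built from bioprocess vocabulary deliberately absent from the
dictionary. Templates use simple clause structure on purpose: closure
(precision = recall = 1) demonstrates that every stage — segmentation,
triggers, patterns, grounding, typing, scoring — composes correctly,
*not* that the system achieves that accuracy on real abstracts, whose
syntax (coordination, apposition, parenthesis, hedging) is far richer.
Real-literature behavior is exercised separately by the bundled
worked-example corpus of sentences from published CHO-glycosylation
abstracts (cited by PMID; one clearly marked synthetic document
supplements the trace-metal coverage).

## Numerical and degenerate-input choices

- Empty documents, empty sections and trigger-free sentences yield
  empty results, never errors; a provider failure on one sentence is
  logged and skipped.
- Precision/recall/F1 are 0 by convention on zero denominators;
  gold matching is greedy one-to-one in input order, duplicates of a
  matched gold count as false positives.
- Within a sentence, duplicates per (affector concept, affected
  concept, trigger) merge; self-relations are dropped.
- Surface-form collisions across concepts abort dictionary loading
  (ambiguity is a curation error, not a runtime choice).
- is_a cycles are fatal; hierarchy depth > 4 only warns, since the
  class DAG allows multiple parents and auxiliary branches.

## Open choices made here

- Abbreviation aliases are scoped per document (not merged globally),
  and only registered when the long form grounds to a concept.
- Reference-list sections are excluded from extraction by default
  (`exclude_sections=("References",)`), configurable.
- In comparisons the compared aspect is linked to *both* compared
  entities; whichever fails to ground simply drops, which in practice
  selects the informative one.
- Entity matching in evaluation is concept-level after normalization —
  the system's own contract — rather than raw-string or span-level.

## Known limitations

Cross-sentence co-reference, part-whole argument propagation, hedging
and speculation detection, and cue-word sense disambiguation are out of
scope. The shallow provider mislocates arguments in deeply nested or
elliptical clauses; the contract exists precisely so a dependency-parse
provider can be substituted without touching the rules. The bundled
dictionary and ontology are working fixtures, not a curated
terminology: scaling to a real corpus requires extending both.
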