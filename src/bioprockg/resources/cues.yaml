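# Positive / negative / negation cue lemmas for correlation typing.
# The three sets must be pairwise disjoint. Noun forms (reduction, loss)
# are listed alongside verbs because cue scanning is lemma-level, not
# POS-aware. "influence" is treated as a directionally positive trigger
# ("parameters that influence afucosylation" reads as a positive impact
# claim), unlike the neutral "impact"/"affect"/"effect".
positive:
  - increase
  - elevate
  - enhance
  - improve
  - high
  - higher
  - highest
  - up-regulate
  - upregulate
  - promote
  - stimulate
  - boost
  - augment
  - positively
  - influence
  - enrich
  - maximize
  - greater
negative:
  - decrease
  - reduce
  - reduction
  - lower
  - low
  - lowest
  - down-regulate
  - downregulate
  - inhibit
  - suppress
  - decline
  - diminish
  - impair
  - lack
  - loss
  - deplete
  - negatively
  - fewer
  - minimize
negation:
  - "no"
  - not
  - never
  - without
  - neither
  - nor
  - cannot
  - none
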