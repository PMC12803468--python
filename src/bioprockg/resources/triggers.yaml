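# Trigger lemmas by category. The inventory is configuration, not code:
# extend these lists to widen coverage. Directional verbs (increase,
# reduce, ...) act as triggers in their own right — "Cell death REDUCES
# productivity" is an impact statement whose trigger also carries the
# sign of the correlation.
impact:
  - cause
  - affect
  - impact
  - effect
  - influence
causal:
  - result
  - lead
  - enable
  - drive
regulation:
  - regulate
  - modulate
  - control
  - increase
  - decrease
  - reduce
  - enhance
  - improve
  - inhibit
  - elevate
  - suppress
  - promote
  - diminish
association:
  - associate
  - contribute
  - involve
  - correlate
  - link
  - show
  - exhibit
comparison:
  - compare
  - than
negation:
  - "no"
  - not
  - never
  - without
  - neither
  - nor
  - cannot
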