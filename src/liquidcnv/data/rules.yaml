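# Ordered myeloid cytogenetic risk rules; first match wins.
#
# complex_min: minimum complexity score (determinate imbalances +
#   indeterminate_weight x dosage-indeterminate abnormalities) for the
#   complex class.  The complex-vs-poor boundary is configuration: clinical
#   per-case labels are not reproducible by any single counting rule.
complex_min: 3
indeterminate_weight: 1.0
rules:
  - predicate: not_evaluable
    class: NOT_EVALUABLE
  - predicate: fusion_only
    class: NO_LOSS_GAIN
  - predicate: complexity
    class: COMPLEX
  - predicate: poor_region
    class: POOR
  - predicate: any_abnormality
    class: INTERMEDIATE
  # a normal (empty) result is intermediate risk in myeloid stratification
  - predicate: default
    class: INTERMEDIATE
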