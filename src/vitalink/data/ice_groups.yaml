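# Default ICE-style infant cause-of-death grouping (approximation; the
# engine accepts any replacement with pairwise-disjoint ICD-10 prefixes).
# Ranges like "P26-P28" expand to every 3-character prefix in the range.
groups:
  - label: immaturity-related
    prefixes: [P05, P07, P22, P26-P28, P77]
  - label: congenital anomalies
    prefixes: [Q]
  - label: asphyxia
    prefixes: [P03, P10, P15, P20-P21, P24]
  - label: infection
    prefixes: [A, B, J, P23, P35-P39]
  - label: SIDS
    prefixes: [R95]
  - label: external
    prefixes: [V, W, X, Y]
fallback: other/ill-defined
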