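# Declarative consensus label map for merging the clusterings of the two
# oscillation experiments (experiment A = short period, higher temporal
# resolution; experiment B = long period).  Cells name significant overlap
# cells (cluster in A, cluster in B) -> consensus cohort; composite names
# (B.C, B.D) mark gene groups split differently by the two systems.
# Unmatched genes of a cluster fall back to the listed background classes;
# everything else present on both arrays defaults to "n" (noisy /
# non-consensus) and genes absent from either experiment get "r".
cells:
  - {a: A, b: A, label: A}
  - {a: A, b: B, label: AB}
  - {a: B, b: B, label: B}
  - {a: B, b: C, label: B.C}
  - {a: C, b: C, label: C}
  - {a: B, b: D, label: B.D}
  - {a: D, b: D, label: D}
fallback:
  B: l.b
  C: cd.n
  D: cd.n
default: n
absent: r
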