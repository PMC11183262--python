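# Example adult luminal signature (curated mouse markers).
# Replace with a reference-derived list for real analyses.
Krt8
Krt18
Krt19
Anxa1
Ly6d
Lgals3
Plet1
Grhl3
Krtdap
Epcam
Cldn3
Cldn4
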