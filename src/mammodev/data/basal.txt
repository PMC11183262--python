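# Example adult basal/myoepithelial signature (curated mouse markers).
# Replace with a reference-derived list for real analyses.
Krt5
Krt14
Trp63
Acta2
Myh11
Mylk
Myl9
Oxtr
Pthlh
Cxcl14
Ndnf
Lmo1
Sostdc1
Wnt10b
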