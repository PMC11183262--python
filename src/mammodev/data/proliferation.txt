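# Proliferation (cell-cycle) program: 13 genes used to flag proliferative
# clusters in the embryonic mammary epithelium and mesenchyme.
Pclaf
Ncapg2
Smc2
Tyms
Tuba1b
Hmgb2
Top2a
Tacc3
Cenph
Cdk1
Tubb5
Diaph3
Cenpf
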