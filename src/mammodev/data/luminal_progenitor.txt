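# Example luminal progenitor (LP) signature.
Notch1
Aldh1a3
Lypd3
Kit
Elf5
Csn3
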