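# Example mature luminal (ML) signature.
Prlr
Cited1
Esr1
Pgr
Foxa1
Areg
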