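#node	age_mya
Eukaryota	1600
Ecdysozoa	700
Mammalia	90
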