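protein	length
H_act1	375
H_kin1	520
H_reg1	210
H_new1	130
H_pat1	340
H_dup1	610
H_dup2	590
H_cat1	450
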