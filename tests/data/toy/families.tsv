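# toy family table: family, species, protein
F01	Hsap	H_act1
F01	Mmus	M_act1
F01	Dmel	D_act1
F01	Cele	C_act1
F01	Scer	Y_act1
F02	Hsap	H_kin1
F02	Mmus	M_kin1
F02	Dmel	D_kin1
F03	Hsap	H_reg1
F03	Mmus	M_reg1
F04	Hsap	H_new1
F05	Hsap	H_pat1
F05	Cele	C_pat1
F06	Hsap	H_dup1
F06	Hsap	H_dup2
F06	Mmus	M_dup1
F06	Scer	Y_dup1
F07	Mmus	M_only1
F08	Hsap	H_cat1
F08	Dmel	D_cat1
F08	Scer	Y_cat1
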