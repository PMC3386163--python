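# species=Hsap
# algorithm=dollo
# family_db=families.tsv
# gain_penalty=1
# loss_penalty=1
# phylostrat=0.1.0
# tree=tree.nwk
protein	species	family	origin_taxon	age_mya	method
H_act1	Hsap	F01	Eukaryota	1600.0	dollo
H_cat1	Hsap	F08	Eukaryota	1600.0	dollo
H_dup1	Hsap	F06	Eukaryota	1600.0	dollo
H_dup2	Hsap	F06	Eukaryota	1600.0	dollo
H_kin1	Hsap	F02	Eukaryota	1600.0	dollo
H_new1	Hsap	F04	Hsap	0.0	dollo
H_pat1	Hsap	F05	Eukaryota	1600.0	dollo
H_reg1	Hsap	F03	Mammalia	90.0	dollo
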