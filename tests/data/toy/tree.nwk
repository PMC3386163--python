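((Hsap,Mmus)Mammalia,(Dmel,Cele)Ecdysozoa,Scer)Eukaryota;
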