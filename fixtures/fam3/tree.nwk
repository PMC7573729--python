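((((fam3_g1:0.11530217804574036,fam3_g2:0.11530217804574036)n3:0.08098364973794786,fam3_g3:0.19628582778368822)n2:0.10974514577470815,fam3_g4:0.30603097355839637)n1:0.42368268119559127,(fam3_g5:0.5400066003151605,(fam3_g6:0.22795084074023614,(fam3_g7:0.02734035240656471,fam3_g8:0.02734035240656471)n6:0.20061048833367143)n5:0.31205575957492426)n4:0.18970705443882724)root;
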