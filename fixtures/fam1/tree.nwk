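((fam1_g1:0.28714485208798607,((fam1_g2:0.047534558667618264,fam1_g3:0.047534558667618264)n3:0.029973699191104777,fam1_g4:0.07750825785872305)n2:0.209636594229263)n1:0.24982577162628491,((fam1_g5:0.007885960788807586,fam1_g6:0.007885960788807586)n5:0.3793267292063596,(fam1_g7:0.2545940273448719,fam1_g8:0.2545940273448719)n6:0.13261866265029526)n4:0.14975793371910376)root;
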