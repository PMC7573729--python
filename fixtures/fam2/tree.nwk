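((fam2_g1:0.189698595627612,fam2_g2:0.189698595627612)n1:0.63453758084594,(((fam2_g3:0.2717601252119349,(fam2_g4:0.07829790529083666,fam2_g5:0.07829790529083666)n5:0.19346221992109822)n4:0.19982920990934133,(fam2_g6:0.19883151816679873,fam2_g7:0.19883151816679873)n6:0.2727578169544775)n3:0.003656857683916203,fam2_g8:0.4752461928051924)n2:0.34898998366835965)root;
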