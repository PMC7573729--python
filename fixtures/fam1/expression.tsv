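	tissue1	tissue2	tissue3	tissue4	tissue5	tissue6	tissue7	tissue8	tissue9	tissue10	tissue11	tissue12
fam1_g1	0.86382763219267089	1.362635349778103	1.2664063617205465	0.43527526822859736	0.86460281822026908	1.227504664172522	0.51120156831694696	1.1469900186831576	1.5548219489158672	0.57219344522225213	0.7002654677495419	1.4094756228468217
fam1_g2	0.78596620865269229	2.4323490181131548	1.39776348835487	0.95869041297155511	0.90138119771697234	0.99466172716427237	0.9309042349568214	1.6246643741314362	0.87348274758604905	1.2943923792739433	0.46118979363028967	2.8252643201512933
fam1_g3	0.81507927294041449	2.2564334783210107	1.8658662483528776	0.74601979006380503	0.88514086763835542	1.1756810523282759	1.4459712582812685	1.341022388060316	1.0627119957586764	1.6648724680227327	0.41467058958768144	2.0548960898851121
fam1_g4	0.8297667038691684	2.4330884276973062	1.9283859548426181	0.88898679905793054	0.79477779700273821	0.89536935928974215	1.0305573966105341	1.2892875007417677	0.82008552466087414	1.9690181287468276	0.33975268358274274	2.1877673459394811
fam1_g5	0.43474546859341512	2.3284900021278032	0.081260685665855467	0.58813508612314025	0.2977368653809403	0.21150858509249104	1.8091289790341123	1.063815257523093	0.90984787823337354	0.82720733754665099	0.93114774111980458	0.41061242921829022
fam1_g6	0.47633977458296201	2.402319670035622	0.082857514508708541	0.57018039859485037	0.28611688358965487	0.19578808136433778	1.7805421594460873	1.0323495207116566	0.9987229377719079	0.8458512822486336	0.88672022615699986	0.4795311259189205
fam1_g7	0.86844671354740244	0.4447740755667336	0.66076138624658487	0.52493305688112812	0.16793175491690432	0.53263100188899937	0.91290036631449978	1.4115455101419447	1.4029077600407684	2.1288686728765649	2.2827017446733051	1.8626405572106666
fam1_g8	0.60653513270103698	0.22757235803515727	0.47771532705593972	0.99757835265282402	1.3127790232755692	0.91645845362540135	1.0819948659401946	0.59885617495392451	1.864715232477866	1.1340151821687503	2.795526494041698	0.51724666861472901
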