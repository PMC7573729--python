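	tissue1	tissue2	tissue3	tissue4	tissue5	tissue6	tissue7	tissue8	tissue9	tissue10	tissue11	tissue12
fam1_g1	0.86382763219267078	1.362635349778103	1.2664063617205463	0.4352752682285973	0.86460281822026896	1.227504664172522	0.51120156831694685	1.1469900186831576	1.5548219489158672	0.57219344522225213	0.7002654677495419	1.4094756228468217
fam1_g2	0.78596620865269218	2.4323490181131548	1.39776348835487	0.95869041297155522	0.90138119771697245	0.99466172716427237	0.9309042349568214	1.6246643741314362	0.87348274758604905	1.2943923792739431	0.46118979363028961	2.8252643201512933
fam1_g3	0.81507927294041438	2.2564334783210107	1.8658662483528776	0.74601979006380503	0.88514086763835542	1.1756810523282759	1.4459712582812685	1.341022388060316	1.0627119957586764	1.6648724680227327	0.41467058958768138	2.0548960898851121
fam1_g4	0.8297667038691684	2.4330884276973066	1.9283859548426181	0.88898679905793054	0.79477779700273821	0.89536935928974215	1.0305573966105339	1.2892875007417677	0.82008552466087414	1.969018128746828	0.33975268358274269	2.1877673459394806
fam1_g5	0.43474546859341512	2.3284900021278032	0.081260685665855398	0.58813508612314025	0.2977368653809403	0.21150858509249101	1.8091289790341123	1.063815257523093	0.90984787823337365	0.82720733754665088	0.93114774111980436	0.41061242921829022
fam1_g6	0.47633977458296201	2.402319670035622	0.082857514508708499	0.57018039859485026	0.28611688358965481	0.1957880813643377	1.7805421594460873	1.0323495207116566	0.99872293777190801	0.8458512822486336	0.88672022615699975	0.4795311259189205
fam1_g7	0.86844671354740244	0.4447740755667336	0.66076138624658476	0.52493305688112812	0.16793175491690429	0.53263100188899926	0.91290036631449956	1.4115455101419447	1.4029077600407684	2.1288686728765649	2.2827017446733047	1.8626405572106663
fam1_g8	0.60653513270103687	0.22757235803515721	0.47771532705593972	0.99757835265282402	1.3127790232755692	0.91645845362540124	1.0819948659401946	0.59885617495392451	1.864715232477866	1.1340151821687503	2.795526494041698	0.51724666861472901
fam2_g1	25.191849484954577	1.1173958124497183	1.5373139899846964	5.0162143872237994	0.084347231760930896	46.913061426251851	0.52866995476935386	0.1207081969573431	1.5313869485862803	0.53398636788865173	0.019196846810723402	3.2031527875880168
fam2_g2	2.3457665991370176	0.27113429227727132	5.7679915868683116	22.470495585796236	0.71695717084947852	2.1038206632987744	46.446661122568422	0.39715103290298231	0.80935867231793435	3.6099324179334897	0.36715752830376408	1.0191179826682959
fam2_g3	0.67498274598474295	2.4030543448415767	0.21533583836395151	0.52915645306277936	1.1648884988227188	1.3004659103481155	9.9154212664588126	0.010155693972298801	0.56085093314908807	0.1131988621739124	0.55230920366875491	0.87315725848304615
fam2_g4	40.733367666566622	0.11895614876125921	1.1696865078032574	89.503311923077973	0.0073222349449090004	0.025940990625782999	2.6557993599497931	3.5338523794409977	21.045668663615409	6.6423472088871947	0.028552651373294401	0.1698936545942481
fam2_g5	2.082971468598557	17.621845889002685	0.41524804701543699	1.8578344947753236	8.1861167188562227	0.44989073102505822	1.2571317667086233	0.0789400592855206	12.755149480399297	2.4195814460137082	2.0559089810597002	0.76170500204593905
fam2_g6	0.055865052180404599	0.1049257726105831	1.9363654712038525	2.7123912220102557	2.5794795262002217	8.3536906236263864	0.58843713199695435	3.5880018046899238	4.2498675231361114	55.692719563515119	0.58922925415068805	3.3838118626263221
fam2_g7	1.7151227336200912	3.3467055445738625	0.029382267921402999	0.0057668014349242002	59.801548259952206	5.1619955306580652	0.0624403108107233	0.12623074243856869	2.5807739563790832	0.64808964605519381	0.4720654448674147	1.0212743943957423
fam2_g8	1.1651918196711912	0.59948218580910262	1.7976682154880139	31.717859050733704	126.66414882102136	1.1851853851676888	1.5625036865226882	7.6294430393954435	3.8114541372295614	17.632892976943438	0.61235391318488674	31.560987223054799
fam3_g1	18.952606554097095	0.049455167915640898	0.050359511012935801	0.046094354976602699	25.713135833265845	20.707449574516406	18.021448993078817	0.044627958691733201	20.491326299816365	19.659921902370336	0.041486396772167297	0.043813550391379803
fam3_g2	18.534457616392363	0.05197000509889	0.045949066217652601	0.046614891833632099	24.385861740640568	22.022260303560792	20.089512401828863	0.047393712178921597	20.151514142893664	19.437854121384799	0.0402824671692684	0.045065253125146899
fam3_g3	19.64506245077574	0.053848715207281302	0.045763221089513501	0.046690846610553297	24.591714532051888	21.411399788400868	18.804273106301629	0.044380341455008798	20.840083755633525	20.578628279583103	0.045619628850435003	0.047846780865536197
fam3_g4	19.430083007281869	0.050176973286851702	0.048497795733185703	0.045732676119390303	25.085353062176328	21.583432036132049	21.405982729917799	0.050484584073767498	19.582876927356239	19.650883367691986	0.049035916529615801	0.048457638749944298
fam3_g5	0.90090671981444137	0.96370472454698863	1.0473230689717068	1.009174405093388	1.1295614288237097	0.97403600746397223	0.93911119677547683	0.92190132454951235	0.94437734753826563	0.82849754542621978	0.96953077438080204	1.0399150846039915
fam3_g6	0.85794250580411424	1.1186227468587513	0.96032715836328719	0.89297548554916872	0.99350425793483454	1.0274677418972331	1.0480311305274943	1.0497575970071886	1.0683617253686437	1.0073269867776269	0.98368555076334119	0.99661415933848685
fam3_g7	1.0100878941101366	0.97153516646952043	0.94035074597901858	0.95800837162834285	1.0586949272778812	0.99667109754281602	1.0749355539207801	1.061470859877933	1.0332756123444118	1.0195247313574862	0.97200276180621437	1.0287274017279664
fam3_g8	1.0120614727703152	1.0114622086835596	0.93674575473053323	0.9586855200750688	1.0552161001509106	1.0250135013332953	1.0871311819286509	1.0610370658249004	1.0342900038695459	1.0381177143729186	0.96661522907913155	1.0549484246961918
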