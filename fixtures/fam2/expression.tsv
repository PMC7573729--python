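	tissue1	tissue2	tissue3	tissue4	tissue5	tissue6	tissue7	tissue8	tissue9	tissue10	tissue11	tissue12
fam2_g1	25.191849484954577	1.1173958124497183	1.5373139899846964	5.0162143872237985	0.084347231760930994	46.913061426251851	0.52866995476935397	0.12070819695734314	1.5313869485862805	0.53398636788865173	0.019196846810723475	3.2031527875880172
fam2_g2	2.3457665991370176	0.27113429227727132	5.7679915868683107	22.470495585796233	0.71695717084947852	2.1038206632987744	46.446661122568429	0.39715103290298237	0.80935867231793446	3.6099324179334897	0.36715752830376414	1.0191179826682961
fam2_g3	0.67498274598474295	2.4030543448415771	0.21533583836395159	0.52915645306277947	1.1648884988227188	1.3004659103481155	9.9154212664588126	0.010155693972298853	0.56085093314908818	0.11319886217391248	0.55230920366875491	0.87315725848304615
fam2_g4	40.733367666566622	0.11895614876125921	1.1696865078032574	89.503311923077959	0.0073222349449090039	0.025940990625783041	2.6557993599497935	3.5338523794409977	21.045668663615412	6.6423472088871947	0.028552651373294456	0.16989365459424818
fam2_g5	2.082971468598557	17.621845889002685	0.41524804701543705	1.8578344947753234	8.1861167188562209	0.44989073102505828	1.2571317667086233	0.078940059285520697	12.755149480399297	2.4195814460137082	2.0559089810596998	0.76170500204593916
fam2_g6	0.055865052180404606	0.1049257726105831	1.9363654712038523	2.7123912220102553	2.5794795262002217	8.3536906236263864	0.58843713199695447	3.5880018046899234	4.2498675231361105	55.692719563515119	0.58922925415068805	3.3838118626263221
fam2_g7	1.7151227336200912	3.3467055445738625	0.029382267921403051	0.0057668014349242964	59.801548259952213	5.1619955306580652	0.062440310810723376	0.12623074243856877	2.5807739563790832	0.64808964605519381	0.4720654448674147	1.0212743943957425
fam2_g8	1.1651918196711912	0.59948218580910262	1.7976682154880139	31.717859050733704	126.66414882102136	1.1851853851676888	1.5625036865226882	7.6294430393954435	3.8114541372295623	17.632892976943438	0.61235391318488686	31.560987223054799
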