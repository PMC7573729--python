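	tissue1	tissue2	tissue3	tissue4	tissue5	tissue6	tissue7	tissue8	tissue9	tissue10	tissue11	tissue12
fam3_g1	18.952606554097098	0.04945516791564096	0.050359511012935829	0.046094354976602706	25.713135833265845	20.707449574516406	18.021448993078817	0.044627958691733201	20.491326299816365	19.659921902370339	0.041486396772167325	0.043813550391379845
fam3_g2	18.534457616392363	0.051970005098890007	0.045949066217652622	0.04661489183363219	24.385861740640571	22.022260303560792	20.089512401828866	0.047393712178921667	20.151514142893664	19.437854121384802	0.040282467169268463	0.045065253125146983
fam3_g3	19.64506245077574	0.053848715207281385	0.045763221089513535	0.04669084661055338	24.591714532051888	21.411399788400868	18.804273106301629	0.044380341455008826	20.840083755633525	20.578628279583103	0.045619628850435065	0.047846780865536245
fam3_g4	19.430083007281869	0.05017697328685173	0.048497795733185731	0.045732676119390352	25.085353062176328	21.583432036132052	21.405982729917799	0.05048458407376754	19.582876927356242	19.650883367691986	0.049035916529615871	0.048457638749944305
fam3_g5	0.90090671981444148	0.96370472454698863	1.0473230689717068	1.009174405093388	1.1295614288237095	0.97403600746397223	0.93911119677547683	0.92190132454951235	0.94437734753826563	0.82849754542621989	0.96953077438080193	1.0399150846039917
fam3_g6	0.85794250580411424	1.1186227468587513	0.9603271583632873	0.89297548554916872	0.99350425793483466	1.0274677418972331	1.0480311305274943	1.0497575970071886	1.0683617253686437	1.0073269867776267	0.98368555076334119	0.99661415933848685
fam3_g7	1.0100878941101366	0.97153516646952043	0.94035074597901869	0.95800837162834274	1.0586949272778812	0.99667109754281591	1.0749355539207801	1.061470859877933	1.0332756123444118	1.0195247313574862	0.97200276180621459	1.0287274017279664
fam3_g8	1.0120614727703152	1.0114622086835596	0.93674575473053334	0.95868552007506891	1.0552161001509106	1.0250135013332953	1.0871311819286507	1.0610370658249004	1.0342900038695459	1.0381177143729186	0.96661522907913155	1.0549484246961918
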