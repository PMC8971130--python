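gene	S1	S2	S3	S4	S5	S6
G001	12.0187420883	15.3670552418	14.4855010818	14.7409268849	10.9978913679	13.5953203042
G002	13.7385795131	14.7889267456	9.5623512398	12.7601243461	11.5538120464	12.0532540428
G003	11.1792687162	12.7355320165	11.6844091326	12.5526294647	10.0816656883	11.2551037513
G004	15.4508442898	16.3862746700	14.1251263716	14.3708515465	14.5015381685	15.6108606935
G005	15.0449525653	17.7905847733	15.0136478127	15.1866669933	15.0018001158	16.0194243007
G006	13.3906627074	14.1784099836	13.0295568019	11.1615305082	14.7228438040	13.3852744036
G007	12.7126089956	14.0888258316	12.6573599760	14.8356728730	15.2884047556	15.2540674257
G008	15.6177077699	13.7809132323	15.4204181871	15.0351893270	13.7795304272	15.5539718720
G009	12.6316917992	15.5375748795	14.0189703254	14.1673012129	15.3056302740	15.2635605033
G010	12.5459650668	13.3700469130	14.0189703254	13.2007867883	12.8401002006	10.9130075102
G011	12.0187420883	13.0040842578	11.9384833845	14.3280350955	13.3186374973	13.4365313696
G012	11.3907536718	11.0194085627	11.3758177831	14.1178845330	13.5674112135	11.3998718020
G013	12.5459650668	13.8642679841	15.7867230039	16.4569102340	14.1282881016	14.0549657787
G014	12.7892277678	12.1634440054	14.0189703254	14.6911135463	13.7795304272	13.9412622552
G015	13.1210618782	14.1784099836	11.9384833845	15.8778839963	12.5241735736	15.9417249319
G016	11.7386509859	11.0194085627	11.9384833845	11.9066903504	11.9541064189	13.8433716328
G017	10.6318457333	9.0791281205	11.3758177831	8.7549935793	6.9338667298	8.9922075867
G018	12.6316917992	12.2894273967	11.6844091326	12.1225047221	12.1190833731	12.5330671200
G019	6.9338667298	9.0791281205	9.5623512398	9.5348837518	9.2358967189	9.8077076129
G020	16.4310503388	15.8722482096	17.4837542461	16.5057544701	15.5126418692	13.9878244283
G021	11.3907536718	10.2744191400	9.5623512398	10.0383229352	9.2358967189	9.5835091383
G022	13.2887853121	9.9060903089	13.1349643999	15.5267078398	12.5241735736	14.8995675243
G023	8.9318677189	6.9338667298	6.9338667298	6.9338667298	6.9338667298	6.9338667298
G024	12.9312424596	9.6793636881	10.4407125657	12.3956148006	14.1665030146	11.2551037513
G025	13.7385795131	13.6617082957	14.4855010818	11.6528151150	9.2358967189	10.9130075102
G026	6.9338667298	6.9338667298	6.9338667298	8.7549935793	6.9338667298	9.5835091383
G027	12.7126089956	12.2894273967	12.9158364692	12.3101965049	14.1665030146	14.2490481490
G028	12.2531955701	11.5082605593	12.5083875107	11.3445176619	6.9338667298	11.8665258954
G029	12.4548207302	9.6793636881	11.3758177831	6.9338667298	9.2358967189	7.9730215819
G030	12.1407262495	14.8984421855	15.3122079336	15.1866669933	15.1804952780	16.6440422178
G031	10.9313675332	11.9762815885	10.4407125657	8.7549935793	11.3024646169	6.9338667298
G032	13.9535891053	15.1124522156	15.8806480949	15.2221755397	16.1012866933	15.3684643771
G033	13.8500860562	14.1784099836	12.3422418636	13.4205003576	13.5674112135	15.0497746568
G034	15.0604933130	14.9115650677	13.7133756749	14.2839089656	14.3099790583	15.4662546268
G035	14.1696231769	14.1230750578	14.7405884896	16.0655157965	13.3849667061	12.0532540428
G036	14.0809666771	14.0298725658	13.4116077292	13.7144858617	14.8219445339	12.5330671200
G037	11.5751636890	14.1892267664	13.2331922060	8.7549935793	13.9203729840	13.3321290505
G038	13.6994095716	12.3676918229	13.9043782875	10.4108035513	12.1190833731	13.1598287709
G039	15.2212281382	13.1440889290	13.1349643999	11.9066903504	14.1282881016	11.4671492555
G040	15.2073337791	13.6771587876	15.3345090446	14.6741194145	12.9317053290	13.9647311796
G041	12.7892277678	13.2919136634	14.1754120028	9.5348837518	12.2671157735	14.2298052394
G042	13.6994095716	15.8140362345	14.4855010818	15.3560663761	15.1616987492	13.9992338956
G043	8.9318677189	8.6486541347	10.4407125657	6.9338667298	6.9338667298	9.8077076129
G044	6.9338667298	6.9338667298	6.9338667298	6.9338667298	6.9338667298	7.9730215819
G045	15.9283854689	14.6391944787	14.8058904281	17.2620035612	13.7795304272	15.4907112738
G046	10.9313675332	15.2112769109	13.7133756749	14.4124338264	14.9146732550	15.9767755799
G047	13.2350152914	12.1634440054	13.4931703025	14.6741194145	14.8690537795	14.4030112713
G048	14.4781094955	14.6470619026	14.7067945645	13.9302390260	14.5311303069	14.0980512723
G049	15.0910814329	14.8651030525	15.1706373625	15.7780274143	17.7708267631	15.5147602319
G050	16.1838705729	13.6924455649	15.7034927171	14.9101359399	17.3109156175	15.9709926228
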