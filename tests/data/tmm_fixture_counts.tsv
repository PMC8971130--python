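gene	S1	S2	S3	S4	S5	S6
G001	11	302	36	88	4	95
G002	37	202	1	22	6	32
G003	6	48	5	19	2	18
G004	122	613	28	68	48	387
G005	92	1624	52	120	68	514
G006	29	132	13	7	56	82
G007	18	124	10	94	83	302
G008	137	100	69	108	29	372
G009	17	340	26	59	84	304
G010	16	75	26	30	15	14
G011	11	58	6	66	21	85
G012	7	14	4	57	25	20
G013	16	106	89	290	37	131
G014	19	32	26	85	29	121
G015	24	132	6	194	12	487
G016	9	14	6	12	8	113
G017	4	3	4	1	0	3
G018	17	35	5	14	9	45
G019	0	3	1	2	1	6
G020	241	429	289	300	97	125
G021	7	8	1	3	1	5
G022	27	6	14	152	12	236
G023	1	0	0	0	0	0
G024	21	5	2	17	38	18
G025	37	92	36	10	1	14
G026	0	0	0	1	0	5
G027	18	35	12	16	38	150
G028	13	20	9	8	0	28
G029	15	5	4	0	1	1
G030	12	218	64	120	77	793
G031	5	28	2	1	5	0
G032	43	253	95	123	146	327
G033	40	132	8	35	25	262
G034	93	220	21	64	42	350
G035	50	127	43	221	22	32
G036	47	119	17	43	60	45
G037	8	133	15	1	32	79
G038	36	37	24	4	9	70
G039	104	64	14	12	37	21
G040	103	93	65	84	16	123
G041	19	71	29	2	10	148
G042	36	412	36	135	76	126
G043	1	2	2	0	0	6
G044	0	0	0	0	0	1
G045	170	182	45	507	29	356
G046	5	271	21	70	64	499
G047	26	32	18	84	62	167
G048	62	183	42	50	49	135
G049	95	213	58	181	465	362
G050	203	94	84	99	338	497
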