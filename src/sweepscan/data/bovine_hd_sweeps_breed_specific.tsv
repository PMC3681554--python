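breed	chrom	start	end	size	n_total	n_fixed	n_variable
Angus	1	1673108	2024737	351629	235	231	4
Angus	1	111659758	111900241	240483	231	221	10
Angus	3	28196188	28405853	209665	207	199	8
Angus	6	6308164	6696861	388697	74	72	2
Angus	8	70780263	71227757	447494	24	24	0
Angus	8	73538014	73760303	222289	288	282	6
Angus	11	99717097	99929710	212613	63	60	3
Angus	14	3550689	3885375	334686	21	21	0
Angus	14	24631146	25173007	541861	387	376	11
Angus	18	200903	406270	205367	117	114	3
Angus	20	70827025	71040113	213088	30	29	1
Angus	21	1186567	1489860	303293	26	25	1
Angus	21	3091822	3417143	325321	308	301	7
Angus	25	39262249	39468067	205818	21	20	1
Angus	27	36633324	36896534	263210	135	130	5
Angus	29	49557166	49922377	365211	70	69	1
Brahman	5	48679627	48903409	223782	249	237	12
Brahman	10	24519718	24794435	274717	20	20	0
Brahman	22	10701509	10963520	262011	88	86	2
Hanwoo	9	1384189	1586988	202799	214	211	3
Hanwoo	22	60772158	61015491	243333	24	23	1
Simmental	1	83467837	83685705	217868	124	118	6
Simmental	2	36576839	36828533	251694	216	206	10
Simmental	2	119873146	120084764	211618	158	151	7
Simmental	2	121398894	121698563	299669	196	188	8
Simmental	5	68631784	68857802	226018	276	267	9
Simmental	7	21101050	21348345	247295	65	63	2
Simmental	7	52426108	52673522	247414	40	38	2
Simmental	8	70246437	70540424	293987	163	158	5
Simmental	10	59147189	59382774	235585	190	182	8
Simmental	10	72811087	73041092	230005	217	210	7
Simmental	13	12236039	12524368	288329	382	369	13
Simmental	13	66468866	66708674	239808	153	146	7
Simmental	15	82007368	82208624	201256	32	32	0
Simmental	16	42555966	42788613	232647	46	44	2
Simmental	16	43767572	44053904	286332	186	181	5
Simmental	17	13291922	13492010	200088	141	136	5
Simmental	19	34588859	35435279	846420	59	57	2
Simmental	22	2788408	3001597	213189	216	214	2
Simmental	25	26433626	26744488	310862	126	120	6
Simmental	25	42202212	42775697	573485	21	21	0
Simmental	28	30480640	30711987	231347	254	243	11
Simmental	29	39045837	39396761	350924	93	91	2
Simmental	29	49052295	49273683	221388	21	20	1
Wagyu	1	197944	574931	376987	321	313	8
Wagyu	1	12544028	12840164	296136	335	325	10
Wagyu	2	71299739	71508079	208340	177	169	8
Wagyu	2	136434039	136676537	242498	22	21	1
Wagyu	3	12027611	12227923	200312	65	64	1
Wagyu	3	113841208	114151444	310236	189	181	8
Wagyu	3	117817862	118017993	200131	114	110	4
Wagyu	4	117846325	118095397	249072	21	20	1
Wagyu	4	119437108	119832270	395162	26	25	1
Wagyu	11	33020266	33264604	244338	307	293	14
Wagyu	11	59513020	59783144	270124	282	269	13
Wagyu	11	103333722	103590033	256311	33	32	1
Wagyu	11	105596531	105828115	231584	23	22	1
Wagyu	12	23283	377340	354057	137	137	0
Wagyu	13	15493906	15739251	245345	305	301	4
Wagyu	13	58016490	58335951	319461	114	110	4
Wagyu	16	51275719	51519519	243800	39	38	1
Wagyu	19	53829568	54065288	235720	25	24	1
Wagyu	22	49088027	49456146	368119	102	98	4
Wagyu	24	36584702	36795576	210874	224	218	6
Wagyu	27	17911399	18114646	203247	304	289	15
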