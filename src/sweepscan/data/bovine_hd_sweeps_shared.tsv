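breeds	chrom	start	end	size	n_total	n_fixed	n_variable	block
Angus	6	5639799	5993214	353415	95	92	3	b01
Simmental,Wagyu,Hanwoo	6	5639799	5993214	353415	95	94	1	b01
Angus,Simmental,Wagyu	6	106844116	107308280	464164	21	20	1	b02
Simmental	7	4344221	4677474	333253	22	21	1	b03
Hanwoo	7	4443937	4838781	394844	90	88	2	b03
Angus	7	51000141	51430242	430101	406	391	15	b04
Simmental	7	51144109	51788442	644333	477	469	8	b04
Wagyu	14	2098182	2588143	489961	29	29	0	b05
Hanwoo	14	2097493	2603935	506442	31	30	1	b05
Angus	16	44463682	44881229	417547	213	203	10	b06
Simmental	16	44693447	45207060	513613	162	158	4	b06
Angus	16	45386065	45652672	266607	248	238	10	b07
Simmental	16	45386065	45677279	291214	286	280	6	b07
Simmental	16	49400423	49679673	279250	22	21	1	b08
Wagyu	16	49400423	49661831	261408	20	20	0	b08
Simmental	16	52629624	52857759	228135	30	30	0	b09
Wagyu	16	52629624	52857759	228135	30	29	1	b09
Wagyu	17	69501174	69703717	202543	116	112	4	b10
Wagyu	17	69953291	70183461	230170	145	140	5	b10
Hanwoo	17	69705850	70283199	577349	421	402	19	b10
Simmental	17	73619837	73975539	355702	24	24	0	b11
Wagyu	17	73761834	74325363	563529	57	55	2	b11
Angus	18	14725181	14973411	248230	107	102	5	b12
Simmental	18	14725181	14973411	248230	107	104	3	b12
Angus	18	53342619	53596733	254114	53	51	2	b13
Simmental	18	53342619	53573919	231300	46	44	2	b13
Angus	19	57106999	57377040	270041	26	25	1	b14
Simmental	19	57065941	57377040	311099	28	28	0	b14
Angus	20	71679859	72012001	332142	37	36	1	b15
Simmental	20	71780338	72012001	231663	29	28	1	b15
Angus	21	2134	742281	740147	422	408	14	b16
Simmental	21	2134	326342	324208	187	179	8	b16
Angus,Simmental	21	1727412	2142823	415411	30	29	1	b17
Angus	21	70948810	71284393	335583	23	22	1	b18
Hanwoo	21	71112766	71575370	462604	32	31	1	b18
Angus	26	21432	718976	697544	242	234	8	b19
Simmental	26	21432	723266	701834	250	244	6	b19
Wagyu	26	21432	225284	203852	30	29	1	b19
Wagyu	26	249534	454031	204497	81	77	4	b19
Hanwoo	26	21432	454031	432599	121	119	2	b19
Simmental	29	1156	558130	556974	155	153	2	b20
Wagyu	29	105179	536644	431465	122	120	2	b20
Hanwoo	29	315440	558130	242690	90	86	4	b20
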