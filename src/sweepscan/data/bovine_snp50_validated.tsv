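chrom	breed	start	end	n_fixed	n_variable	size	block
1	Angus	1673108	2024737	313	8	351629	v1
13	Wagyu	15493906	15739251	301	4	245345	v2
16	Angus	45386065	45652672	238	10	266607	v3
16	Simmental	45386065	45677279	280	6	291214	v3
16	Simmental	52629624	52857759	30	0	228135	v4
16	Wagyu	52629624	52857759	29	1	228135	v4
18	Angus	14725181	14973411	102	5	248230	v5
18	Simmental	14725181	14973411	104	3	248230	v5
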