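breeds	chrom	start	end	n_snp	size	block	size_consistent
Angus	1	1712261	2013659	11	301398	b01	1
Limousin	2	5974885	6344425	7	369540	b02	1
Brown Swiss	2	73436684	73978469	10	541785	b03	1
Hanwoo	3	19860064	20175158	5	315094	b04	1
Hanwoo	3	112997892	113219287	5	221395	b05	1
Brown Swiss	4	61098696	61376132	9	277436	b06	1
Hereford	6	70655812	70865694	6	209882	b07	1
Brown Swiss	6	75830633	76696893	9	866260	b08	1
Salers	6	75996320	76696893	8	700573	b08	1
Jersey	6	105390830	105730372	8	339542	b09	1
Limousin	7	40250259	40485825	7	235566	b10	1
Jersey	7	45439468	45828427	10	388959	b11	1
Holstein	7	72908532	73126315	7	217783	b12	1
Brown Swiss	11	25577969	25941999	10	364030	b13	1
Jersey	12	1113009	1436093	8	323084	b14	1
Angus,Salers,Shorthorn,Simmental	12	25878820	26236394	7	357574	b15	1
Brahman	12	36287533	36989957	14	702424	b16	1
Holstein	13	15456721	15683571	6	226850	b17	1
Braunvieh	14	28674493	28960475	5	285982	b18	1
Brown Swiss	14	42739573	43140076	9	400503	b19	1
Braunvieh	16	39714165	39898049	3	389103	b20	0
Salers	16	43200419	43618684	9	418265	b21	1
Jersey	16	45376614	45874144	8	497530	b22	1
Angus,Holstein,Limousin,Simmental	16	45425579	45874144	7	448565	b22	1
Hereford	16	45464423	45874144	6	409721	b22	1
Hanwoo	16	52535473	52742523	4	207050	b23	1
Hanwoo	18	14526709	14847049	5	320340	b24	1
Limousin	19	37301353	37520214	6	218861	b25	1
Brahman	19	43376032	43835219	10	459187	b26	1
Angus,Holstein,Shorthorn	24	63576	320143	6	256567	b27	1
Braunvieh,Charolais,Finnish Ayrshire,Hanwoo	24	105589	320143	5	214554	b27	1
Angus,Holstein,Salers,Shorthorn	27	25075449	25295935	6	220486	b28	1
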