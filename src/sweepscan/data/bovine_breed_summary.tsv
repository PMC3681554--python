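breed	origin	primary_use	run_length	n_monomorphic	n_snp50_individuals	n_hd_individuals
Angus	Scotland	Beef	6	8443	2918	23
Braunvieh	Switzerland	Beef	5	7405	142
Charolais	France	Beef	5	5884	44
Hanwoo	Korea	Beef, Draught	5	8353	48	11
Hereford	UK	Beef	6	8154	812
Limousin	France	Beef	6	8430	261
Salers	France	Beef	6	8409	72
Shorthorn	UK	Beef, Dairy	6	8558	108
Simmental	Switzerland	Beef, Dairy	6	6599	123	6
Brown Swiss	Switzerland	Dairy	9	12553	74
Finnish Ayrshire	Scotland	Dairy	5	6185	599
Holstein	Netherlands	Dairy	6	8587	995
Jersey	Jersey	Dairy	8	12547	78
Wagyu	Japan	Beef, Draught				10
Brahman	USA	Beef	10	13006	99	8
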