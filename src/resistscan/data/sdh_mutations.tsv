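gene	residue	wild_codon	mutant_codon	wild_aa	mutant_aa	label	first_detected_year
sdhB	146	CAT	CAA	H	Q	H146Q	2021
sdhB	212	AGC	ATC	S	I	S212I	2021
sdhB	258	CAT	TAT	H	Y	H258Y	2024
sdhB	260	ATC	ACC	I	T	I260T	2020
sdhB	260	ATC	GTC	I	V	I260V	2021
sdhB	285	GCA	TCA	A	S	A285S	2017
sdhD	116	GAC	GGC	D	G	D116G	2020
sdhD	116	GAC	GAA	D	E	D116E	2024
sdhD	116	GAT	GAA	D	E	D116E	2024
sdhD	116	GAC	AAC	D	N	D116N	2020
sdhD	119	CGT	TGT	R	C	R119C	2020
sdhD	119	CGT	CTT	R	L	R119L	2020
sdhD	119	CGT	GGT	R	G	R119G	2024
sdhD	119	CGT	CCT	R	P	R119P	2020
sdhD	119	CGT	CAT	R	H	R119H	2020
sdhD	120	CCC	CTC	P	L	P120L	2024
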