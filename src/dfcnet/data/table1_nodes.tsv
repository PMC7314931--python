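seed	node	cluster_size	ba	peak_t	x	y	z
Broca	IFGtriang.L	1252	48	39.27	-51	21	15
Broca	TPOsup.R	128	38	14.61	48	21	18
Broca	IFGtriang.R	80	14	11.53	57	30	9
Broca	MTG.L	307	22	11.20	-60	-42	6
Broca	MTG.R	153	21	10.43	69	-36	-3
Broca	SFGmed.L	99	9	10.07	0	45	39
Broca	ANG.R	51		8.93	39	-66	36
Wernicke	SMG.L	786	40	37.17	-54	-51	30
Wernicke	SMG.R	391	48	13.19	51	-42	30
Wernicke	MFG.L	157	9	12.58	-42	12	45
Wernicke	ORBinf.R	58		12.15	51	33	-15
Wernicke	Cerebellum.R	170		11.48	33	-69	-42
Wernicke	ORBinf.L	191	47	10.58	-39	42	-15
Wernicke	IFGoperc.R	59	44	10.43	57	18	12
Wernicke	MFG.R	115	46	10.31	42	36	33
Wernicke	CUN.L	50		9.91	-9	-75	36
Wernicke	Cerebellum.L	128		9.55	-18	-78	-39
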