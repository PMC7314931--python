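state	node_i	node_j	mean_ebg	sd_ebg	mean_lbg	sd_lbg	p	d
1	ANG.R	MFG.R	0.31	0.18	0.07	0.15	1.2e-3	1.45
1	IFGtriang.L	MTG.R	0.45	0.15	0.18	0.21	2.2e-3	1.48
1	TPOsup.R	SFGmed.L	0.51	0.19	0.24	0.18	2.4e-3	1.46
1	TPOsup.R	CUN.L	0.36	0.20	0.09	0.17	1.4e-3	1.45
1	MTG.L	MTG.R	0.60	0.20	0.24	0.24	1.2e-3	1.63
1	MTG.L	IFGoperc.R	0.48	0.28	0.02	0.21	1.0e-3	1.86
1	MTG.R	SFGmed.L	0.47	0.28	0.08	0.27	1.6e-3	1.42
1	MTG.R	ORBinf.R	0.42	0.15	0.01	0.28	1.0e-4	1.83
1	MTG.R	IFGoperc.R	0.43	0.19	0.14	0.19	1.6e-3	1.53
1	IFGoperc.R	MFG.R	0.48	0.14	0.18	0.14	2.8e-3	2.14
2	MTG.L	IFGtriang.R	0.40	0.19	0.12	0.18	2.4e-3	1.51
2	MTG.L	IFGoperc.R	0.37	0.22	0.07	0.19	1.8e-3	1.46
3	IFGtriang.L	SFGmed.L	0.52	0.17	0.27	0.17	2.4e-3	1.47
3	IFGtriang.L	Cerebellum.R	0.33	0.06	0.15	0.17	1.8e-3	1.41
3	TPOsup.R	MTG.L	0.57	0.17	0.27	0.14	2.0e-4	1.76
3	TPOsup.R	MTG.R	0.55	0.18	0.25	0.20	1.0e-3	1.58
3	TPOsup.R	Cerebellum.L	0.44	0.22	0.12	0.19	8.0e-4	1.56
3	TPOsup.R	IFGoperc.R	0.50	0.16	0.26	0.19	2.4e-3	1.37
3	MTG.R	IFGoperc.R	0.45	0.20	0.12	0.23	6.0e-4	1.53
3	IFGtriang.R	Cerebellum.R	0.27	0.11	0.03	0.14	4.0e-4	1.91
3	Cerebellum.L	IFGoperc.R	0.41	0.21	0.16	0.14	1.2e-3	1.40
3	Cerebellum.R	ORBinf.R	0.32	0.11	0.10	0.17	8.0e-4	1.54
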