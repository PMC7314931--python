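metric	state	mean_ebg	sd_ebg	mean_lbg	sd_lbg	p	significant	d
cw	1	0.27	0.05	0.22	0.04	5.00e-3	1	1.10
cw	2	0.25	0.05	0.21	0.04	2.40e-2	0
cw	3	0.27	0.05	0.21	0.04	2.00e-3	1	1.33
cw	4	0.26	0.04	0.23	0.04	6.44e-2	0
lw	1	5.10	0.40	6.54	1.09	6.00e-4	1	1.75
lw	2	5.65	1.85	6.16	1.43	3.18e-1	0
lw	3	5.12	0.84	6.43	1.45	1.36e-2	0
lw	4	5.51	1.80	5.86	0.79	3.20e-1	0
eglob	1	0.24	0.03	0.18	0.02	2.00e-4	1	2.35
eglob	2	0.22	0.04	0.19	0.03	5.00e-2	0
eglob	3	0.24	0.04	0.18	0.03	2.80e-3	1	1.70
eglob	4	0.23	0.04	0.20	0.03	4.04e-2	0
eloc	1	0.27	0.05	0.20	0.04	1.20e-3	1	1.55
eloc	2	0.25	0.06	0.20	0.04	2.20e-2	0
eloc	3	0.27	0.05	0.19	0.04	2.20e-3	1	1.77
eloc	4	0.25	0.05	0.22	0.04	4.46e-2	0
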