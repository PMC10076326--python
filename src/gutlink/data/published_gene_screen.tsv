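tissue	gene	r_abs	p_abs	r_slope	p_slope	bold
eWAT	Cldn22	0.83	0.04	0.72	0.11	1
eWAT	Prkag3	0.81	0.05	0.65	0.17	1
eWAT	Scpep1	0.74	0.09	0.59	0.22	1
eWAT	Srpx2	0.71	0.11	0.53	0.27	1
eWAT	Mfsd7a	0.70	0.12	0.56	0.25	1
eWAT	Sfrp5	0.69	0.13	0.54	0.27	0
eWAT	Duoxa1	0.66	0.15	0.52	0.29	0
eWAT	Zdhhc2	0.65	0.16	0.51	0.30	0
eWAT	B430212C06Rik	0.65	0.17	0.53	0.28	0
eWAT	Syp	0.64	0.17	0.46	0.35	0
eWAT	Tmem45b	0.64	0.17	0.51	0.30	0
eWAT	Aldh9a1	0.62	0.19	0.51	0.30	0
eWAT	Dap	0.23	0.66	0.12	0.83	0
iWAT	Cpne2	-0.35	0.49	0.33	0.52	0
iWAT	Pus10	-0.30	0.56	-0.30	0.56	0
iWAT	Gabrr2	-0.24	0.65	-0.29	0.58	0
BAT	Lox	0.96	<0.01	0.92	0.01	1
BAT	Tgm2	0.91	0.01	0.84	0.03	1
BAT	Gpx8	0.42	0.40	0.23	0.66	0
liver	Or7d12-ps1	-0.96	<0.01	-0.95	<0.01	1
liver	Cryl1	0.85	0.03	0.90	0.01	1
liver	Pepd	0.79	0.06	0.85	0.03	1
liver	Cblc	0.77	0.07	0.69	0.13	1
liver	Apoa4	0.68	0.14	0.70	0.12	1
liver	Wfdc2	0.45	0.37	0.36	0.49	0
liver	Sephs2	0.38	0.46	0.47	0.35	0
liver	Pyroxd2	0.32	0.54	0.12	0.82	0
liver	Pyroxd2	0.32	0.54	0.12	0.82	0
liver	Ephx1	0.31	0.54	0.23	0.67	0
liver	Tex2	-0.27	0.60	-0.44	0.38	0
liver	Coq8a	-0.26	0.61	-0.31	0.55	0
liver	Unc119	0.26	0.62	0.04	0.93	0
liver	Plin2	0.23	0.66	0.05	0.93	0
liver	L2hgdh	0.23	0.67	0.13	0.80	0
liver	Nars2	0.19	0.71	0.21	0.68	0
liver	Atp9a	0.19	0.72	0.01	0.98	0
liver	Acp5	0.19	0.72	0.33	0.53	0
liver	Serinc2	-0.10	0.85	-0.26	0.61	0
liver	Cyp3a44	0.09	0.86	-0.07	0.90	0
liver	Cyp3a11	0.09	0.87	-0.07	0.89	0
liver	P2ry1	-0.08	0.88	-0.18	0.74	0
liver	Cyp3a41b	0.08	0.88	-0.08	0.88	0
liver	Serpina6	0.08	0.88	0.00	1.00	0
liver	Cyp3a41a	0.08	0.89	-0.08	0.88	0
liver	Cyp3a16	0.06	0.92	-0.10	0.85	0
liver	Slc35f2	0.04	0.94	-0.16	0.76	0
muscle	Tmed10	-0.30	0.56	-0.41	0.42	0
duodenum	Nlrc5	0.90	0.02	0.78	0.07	1
duodenum	Tnk1	-0.86	0.03	-0.84	0.03	1
duodenum	Wfs1	0.81	0.05	0.83	0.04	1
duodenum	Gm5475	-0.75	0.09	-0.88	0.02	1
duodenum	St6gal1	-0.68	0.14	-0.46	0.36	0
duodenum	Pccb	0.53	0.28	0.54	0.27	0
duodenum	Slc11a2	-0.52	0.28	-0.73	0.10	1
duodenum	Wdr83	0.51	0.30	0.47	0.34	0
duodenum	Lax1	-0.49	0.32	-0.30	0.56	0
duodenum	Prkacb	0.31	0.54	0.28	0.59	0
duodenum	Fyn	0.27	0.60	0.17	0.75	0
duodenum	Stk3	0.17	0.75	0.08	0.88	0
duodenum	Cyba	0.15	0.78	-0.06	0.92	0
duodenum	Cyp4b1-ps2	-0.14	0.79	-0.16	0.76	0
duodenum	Tbc1d31	0.10	0.85	-0.15	0.77	0
ileum	Ccdc146	-0.48	0.33	-0.37	0.47	0
ileum	Tcf23	-0.30	0.56	-0.23	0.66	0
ileum	1700016C15Rik	0.04	0.93	0.25	0.64	0
ileum	Irf1	0.04	0.94	-0.10	0.85	0
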