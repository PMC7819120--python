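amino_acid	codon	count	rscu	high_frequency
Ala	GCT	482	1.71	1
Ala	GCC	186	0.66	0
Ala	GCA	326	1.15	0
Ala	GCG	136	0.48	0
Cys	TGT	170	1.47	1
Cys	TGC	61	0.53	0
Asp	GAT	677	1.57	1
Asp	GAC	183	0.43	0
Glu	GAA	820	1.48	1
Glu	GAG	290	0.52	0
Phe	TTT	749	1.32	1
Phe	TTC	386	0.68	0
Gly	GGT	482	1.34	0
Gly	GGC	162	0.45	0
Gly	GGA	552	1.54	1
Gly	GGG	241	0.67	0
His	CAT	386	1.48	1
His	CAC	135	0.52	0
Ile	ATT	874	1.48	1
Ile	ATC	344	0.58	0
Ile	ATA	558	0.94	0
Lys	AAA	763	1.47	1
Lys	AAG	274	0.53	0
Leu	TTA	673	1.88	1
Leu	TTG	458	1.28	0
Leu	CTT	456	1.28	0
Leu	CTC	135	0.38	0
Leu	CTA	288	0.81	0
Leu	CTG	135	0.38	0
Met	ATG	500	1.00	0
Trp	TGG	386	1.00	0
Asn	AAT	775	1.57	1
Asn	AAC	214	0.43	0
Pro	CCT	331	1.51	1
Pro	CCC	166	0.76	0
Pro	CCA	257	1.18	0
Pro	CCG	120	0.55	0
Gln	CAA	550	1.52	1
Gln	CAG	173	0.48	0
Arg	CGT	280	1.38	0
Arg	CGC	76	0.37	0
Arg	CGA	276	1.36	0
Arg	CGG	88	0.43	0
Arg	AGA	360	1.77	1
Arg	AGG	139	0.68	0
Ser	TCT	423	1.65	1
Ser	TCC	252	0.99	0
Ser	TCA	311	1.22	0
Ser	TCG	160	0.63	0
Ser	AGT	299	1.17	0
Ser	AGC	90	0.35	0
Thr	ACT	421	1.59	1
Thr	ACC	194	0.73	0
Thr	ACA	329	1.24	0
Thr	ACG	116	0.44	0
Val	GTT	421	1.51	0
Val	GTC	114	0.41	0
Val	GTA	430	1.54	1
Val	GTG	152	0.54	0
Tyr	TAT	617	1.59	1
Tyr	TAC	157	0.41	0
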