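amino_acid	codon	high_count	high_rscu	low_count	low_rscu	delta_rscu	high_expression
Ala	GCT	4	1.45	4	1.00	0.45	1
Ala	GCC	1	0.36	3	0.75	-0.39	0
Ala	GCA	4	1.45	6	1.50	-0.05	0
Ala	GCG	2	0.73	3	0.75	-0.02	0
Cys	TGT	0	0.00	3	2.00	-2.00	0
Cys	TGC	0	0.00	0	0.00	0.00	0
Asp	GAT	7	2.00	0	0.00	2.00	1
Asp	GAC	0	0.00	3	2.00	-2.00	0
Glu	GAA	8	1.33	12	1.85	-0.52	0
Glu	GAG	4	0.67	1	0.15	0.52	1
Phe	TTT	13	1.53	4	1.33	0.20	1
Phe	TTC	4	0.47	2	0.67	-0.20	0
Gly	GGC	1	0.36	1	0.21	0.15	1
Gly	GGA	4	1.45	9	1.89	-0.44	0
Gly	GGG	2	0.73	4	0.84	-0.11	0
Gly	GGT	4	1.45	5	1.05	0.40	1
His	CAT	0	0.00	5	1.67	-1.67	0
His	CAC	1	2.00	1	0.33	1.67	1
Ile	ATT	14	1.83	8	1.41	0.42	1
Ile	ATC	2	0.26	2	0.35	-0.09	0
Ile	ATA	7	0.91	7	1.24	-0.33	0
Lys	AAA	9	1.64	14	1.56	0.08	1
Lys	AAG	2	0.36	4	0.44	-0.08	0
Leu	TTA	8	1.78	4	1.71	0.07	0
Leu	TTG	8	1.78	4	1.71	0.07	0
Leu	CTT	7	1.56	6	2.57	-1.01	0
Leu	CTC	0	0.00	0	0.00	0.00	0
Leu	CTA	3	0.67	0	0.00	0.67	1
Leu	CTG	1	0.22	0	0.00	0.22	1
Met	ATG	6	1.00	8	1.00	0.00	0
Asn	AAT	4	1.33	2	1.33	0.00	0
Asn	AAC	2	0.67	1	0.67	0.00	0
Pro	CCT	4	1.60	5	1.54	0.06	0
Pro	CCC	1	0.40	2	0.62	-0.22	0
Pro	CCA	5	2.00	2	0.62	1.38	1
Pro	CCG	0	0.00	4	1.23	-1.23	0
Gln	CAA	6	2.00	4	1.00	1.00	1
Gln	CAG	0	0.00	4	1.00	-1.00	0
Arg	CGT	4	1.20	9	1.59	-0.39	0
Arg	CGC	0	0.00	1	0.18	-0.18	0
Arg	CGA	9	2.70	9	1.59	1.11	1
Arg	CGG	0	0.00	0	0.00	0.00	0
Arg	AGA	6	1.80	11	1.94	-0.14	0
Arg	AGG	1	0.30	4	0.71	-0.41	0
Ser	TCT	6	1.89	6	1.71	0.18	1
Ser	TCC	3	0.95	3	0.86	0.09	1
Ser	TCA	1	0.32	4	1.14	-0.82	0
Ser	TCG	3	0.95	3	0.86	0.09	1
Ser	AGT	6	1.89	5	1.43	0.46	1
Ser	AGC	0	0.00	0	0.00	0.00	0
Thr	ACT	5	2.50	1	0.40	2.10	1
Thr	ACC	0	0.00	3	1.20	-1.20	0
Thr	ACA	0	0.00	6	2.40	-2.40	0
Thr	ACG	3	1.50	0	0.00	1.50	1
Val	GTT	9	2.57	4	1.45	1.12	1
Val	GTC	0	0.00	1	0.36	-0.36	0
Val	GTA	3	0.86	6	2.18	-1.32	0
Val	GTG	2	0.57	0	0.00	0.57	1
Trp	TGG	5	1.00	5	1.00	0.00	0
Tyr	TAT	7	2.00	6	1.71	0.29	1
Tyr	TAC	0	0.00	1	0.29	-0.29	0
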