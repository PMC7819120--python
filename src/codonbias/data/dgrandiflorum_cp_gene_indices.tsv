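gene	gc	gc3	gc3s	enc
accD	0.36	0.31	0.28	50.99
atpA	0.42	0.31	0.29	49.59
atpB	0.42	0.29	0.27	47.81
atpE	0.39	0.27	0.25	47.65
atpF	0.38	0.34	0.32	44.90
atpI	0.38	0.27	0.24	46.31
ccsA	0.32	0.25	0.20	46.36
cemA	0.32	0.31	0.27	56.82
clpP	0.45	0.34	0.31	55.82
matK	0.31	0.26	0.23	47.53
ndhA	0.36	0.25	0.22	42.71
ndhB	0.37	0.32	0.27	47.37
ndhC	0.36	0.26	0.20	41.24
ndhD	0.36	0.29	0.24	48.99
ndhE	0.34	0.23	0.20	52.21
ndhF	0.33	0.24	0.20	44.71
ndhG	0.36	0.26	0.22	43.72
ndhH	0.39	0.30	0.25	51.44
ndhI	0.37	0.28	0.26	50.38
ndhJ	0.41	0.35	0.30	57.52
ndhK	0.40	0.30	0.27	51.77
petA	0.39	0.32	0.30	50.42
petB	0.43	0.36	0.30	45.84
petD	0.38	0.24	0.21	40.60
psaA	0.44	0.35	0.30	50.76
psaB	0.42	0.34	0.29	51.35
psbA	0.43	0.34	0.30	40.89
psbB	0.43	0.30	0.25	47.36
psbC	0.45	0.33	0.30	46.17
psbD	0.44	0.35	0.30	46.28
rbcL	0.44	0.31	0.29	49.45
rpl14	0.39	0.26	0.24	49.88
rpl16	0.44	0.27	0.21	41.65
rpl20	0.37	0.29	0.26	43.10
rpl22	0.36	0.30	0.24	47.84
rpoA	0.36	0.29	0.26	48.30
rpoB	0.40	0.30	0.28	50.41
rpoC1	0.38	0.28	0.25	48.97
rpoC2	0.38	0.29	0.27	50.39
rps11	0.45	0.26	0.22	50.83
rps14	0.41	0.32	0.29	40.28
rps18	0.35	0.24	0.21	37.11
rps2	0.38	0.26	0.23	45.79
rps3	0.36	0.26	0.24	48.96
rps4	0.39	0.27	0.26	51.15
rps7	0.41	0.24	0.21	46.08
rps8	0.37	0.25	0.22	42.77
ycf1	0.32	0.29	0.25	49.67
ycf2	0.38	0.37	0.34	53.44
ycf3	0.40	0.49	0.46	61.00
ycf4	0.40	0.34	0.31	51.36
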