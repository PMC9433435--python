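# Amino-acid physicochemical property values used by the radical-change scan.
# One row per property; columns are the 20 amino acids (one-letter codes).
# Values are taken from the published compilations named in the source
# column (as collected in standard amino-acid index collections).
property	source	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
equilibrium constant (ionisation of COOH)	pK1 of the alpha-carboxyl group (standard biochemical tables)	2.34	2.17	2.02	1.88	1.96	2.17	2.19	2.34	1.82	2.36	2.36	2.18	2.28	1.83	1.99	2.21	2.09	2.83	2.20	2.32
solvent accessible reduction ratio	Mean fractional area loss on folding, Rose et al. (1985)	0.74	0.64	0.63	0.62	0.91	0.62	0.62	0.72	0.78	0.88	0.85	0.52	0.85	0.88	0.64	0.66	0.70	0.85	0.76	0.86
buriedness	Proportion of buried residues, Chothia (1976)	0.38	0.01	0.12	0.15	0.50	0.07	0.18	0.36	0.17	0.60	0.45	0.03	0.40	0.50	0.18	0.22	0.23	0.27	0.15	0.54
hydropathy	Kyte & Doolittle (1982)	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
molecular weight	Free amino-acid molecular weight (Da)	89.1	174.2	132.1	133.1	121.2	146.2	147.1	75.1	155.2	131.2	131.2	146.2	149.2	165.2	115.1	105.1	119.1	204.2	181.2	117.1
molecular volume	Grantham (1974)	31	124	56	54	55	85	83	3	96	111	111	119	105	132	32.5	32	61	170	136	84
polarity	Grantham (1974)	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
polar requirement	Woese (1973)	7.0	9.1	10.0	13.0	4.8	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5.0	6.6	7.5	6.6	5.2	5.4	5.6
isoelectric point	pI of the free amino acid (standard biochemical tables)	6.00	10.76	5.41	2.77	5.07	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.60	5.89	5.66	5.96
bulkiness	Zimmerman et al. (1968)	11.50	14.28	12.82	11.68	13.46	14.45	13.57	3.40	13.69	21.40	21.40	15.71	16.25	19.80	17.43	9.47	15.77	21.67	18.03	21.57
composition	Grantham (1974)	0	0.65	1.33	1.38	2.75	0.89	0.92	0.74	0.58	0	0	0.33	0	0	0.39	1.42	0.71	0.13	0.20	0
alpha-helical tendencies	Chou & Fasman (1978) P-alpha	1.42	0.98	0.67	1.01	0.70	1.11	1.51	0.57	1.00	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
beta-structure tendencies	Chou & Fasman (1978) P-beta	0.83	0.93	0.89	0.54	1.19	1.10	0.37	0.75	0.87	1.60	1.30	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.70
turn tendencies	Chou & Fasman (1978) P-turn	0.66	0.95	1.56	1.46	1.19	0.98	0.74	1.56	0.95	0.47	0.59	1.01	0.60	0.60	1.52	1.43	0.96	0.96	1.14	0.50
surrounding hydrophobicity	Ponnuswamy et al. (1980)	12.97	11.72	11.42	10.85	14.63	11.76	11.89	12.43	12.16	15.67	14.90	11.36	14.39	14.00	11.37	11.23	11.69	13.93	13.42	15.71
refractive index	Molar refractivity, McMeekin et al. (1964)	4.34	26.66	13.28	12.00	35.77	17.56	17.26	0.00	21.81	19.06	18.78	21.29	21.64	29.40	10.93	6.35	11.01	42.53	31.53	13.92
normalized consensus hydrophobicity	Eisenberg et al. (1984)	0.62	-2.53	-0.78	-0.90	0.29	-0.85	-0.74	0.48	-0.40	1.38	1.06	-1.50	0.64	1.19	0.12	-0.18	-0.05	0.81	0.26	1.08
partial specific volume	Cohn & Edsall (1943)	0.748	0.666	0.619	0.579	0.631	0.674	0.643	0.632	0.670	0.884	0.884	0.789	0.708	0.774	0.774	0.613	0.689	0.734	0.712	0.847
average flexibility index	Bhaskaran & Ponnuswamy (1988)	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.420	0.386
transfer free energy to surface	Janin (1979)	0.3	-1.4	-0.5	-0.6	0.9	-0.7	-0.7	0.3	-0.1	0.7	0.5	-1.8	0.4	0.5	-0.3	-0.1	-0.2	0.3	-0.4	0.6
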