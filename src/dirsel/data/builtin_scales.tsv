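symbol	name	category	unit	source	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
h	Hydropathy	Hydrophobicity		AAindex:KYTJ820101	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
Hp	Surrounding hydrophobicity	Hydrophobicity	kcal/mol	AAindex:PONP800101	12.28	11.49	11.00	10.97	14.93	11.28	11.19	12.01	12.84	14.77	14.10	10.80	14.33	13.43	11.19	11.26	11.65	12.95	13.29	15.07
Ht	Thermodynamic transfer hydrophobicity	Hydrophobicity	kcal/mol	AAindex:JOND750101	0.87	0.85	0.09	0.66	1.52	0.00	0.67	0.10	0.87	3.15	2.17	1.64	1.67	2.87	2.77	0.07	0.07	3.77	2.67	1.87
pK'	Equilibrium constant	Ionization Constants	pH units	AAindex:JOND750102	2.34	1.18	2.02	2.01	1.65	2.17	2.19	2.34	1.82	2.36	2.36	2.18	2.28	1.83	1.99	2.21	2.10	2.38	2.20	2.32
pHi	Isoelectric point	Ionization Constants	pH units	AAindex:ZIMJ680104	6.00	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.66	5.89	5.66	5.96
Bl	Bulkiness	Molecular Size & Composition	A^2	AAindex:ZIMJ680102	11.50	14.28	12.82	11.68	13.46	14.45	13.57	3.40	13.69	21.40	21.40	15.71	16.25	19.80	17.43	9.47	15.77	21.67	18.03	21.57
c	Composition	Molecular Size & Composition		AAindex:GRAR740101	0.00	0.65	1.33	1.38	2.75	0.89	0.92	0.74	0.58	0.00	0.00	0.33	0.00	0.00	0.39	1.42	0.71	0.13	0.20	0.00
Mw	Molecular weight	Molecular Size & Composition	Da	AAindex:FASG760101	89.09	174.20	132.12	133.10	121.15	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.24	181.19	117.15
V0	Partial specific volume	Molecular Size & Composition	m^3/mol x 10^-6	AAindex:BULH740102	0.691	0.728	0.596	0.558	0.624	0.649	0.632	0.592	0.646	0.809	0.842	0.767	0.709	0.756	0.730	0.594	0.655	0.743	0.743	0.777
El	Long range energy	Non-bonded Energy	kcal/mol	AAindex:OOBM770103	-0.491	-0.554	-0.382	-0.356	-0.670	-0.405	-0.371	-0.534	-0.540	-0.762	-0.650	-0.300	-0.659	-0.729	-0.463	-0.455	-0.515	-0.839	-0.656	-0.728
Esm	Short and medium range energy	Non-bonded Energy	kcal/mol	AAindex:OOBM770102	-1.404	-0.921	-1.178	-1.162	-1.365	-1.116	-1.163	-1.364	-1.215	-1.189	-1.315	-1.074	-1.303	-1.135	-1.236	-1.297	-1.252	-1.030	-1.030	-1.254
Et	Total non-bonded energy	Non-bonded Energy	kcal/mol	AAindex:OOBM770101	-1.895	-1.475	-1.560	-1.518	-2.035	-1.521	-1.535	-1.898	-1.755	-1.951	-1.966	-1.374	-1.963	-1.864	-1.699	-1.753	-1.767	-1.869	-1.686	-1.981
Pr	Polar requirement	Polarity & Polarizability		AAindex:WOEC730101	7.0	9.1	10.0	13.0	5.5	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5.0	6.6	7.5	6.6	5.3	5.7	5.6
p	Polarity	Polarity & Polarizability		AAindex:GRAR740102	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
mu	Refractive index	Polarity & Polarizability		AAindex:MCMT640101	4.34	26.66	13.28	12.00	35.77	17.56	17.26	0.00	21.81	19.06	18.78	21.29	21.64	29.40	10.93	6.35	11.01	42.53	31.53	13.92
Pa	Alpha-helical tendency	Secondary Structure		AAindex:CHOP780201	1.42	0.98	0.67	1.01	0.70	1.11	1.51	0.57	1.00	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
Pb	Beta-structure tendency	Secondary Structure		AAindex:CHOP780202	0.83	0.93	0.89	0.54	1.19	1.10	0.37	0.75	0.87	1.60	1.30	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.70
Pc	Coil tendency	Secondary Structure		AAindex:CHAM830101	0.71	1.06	1.37	1.21	1.19	0.87	0.84	1.52	1.07	0.66	0.69	0.99	0.59	0.71	1.61	1.34	1.08	0.76	1.07	0.63
Ca	Helical contact area	Secondary Structure	A^2	AAindex:ROSG850101 (proxy)	86.6	162.2	103.3	97.8	132.3	119.2	113.9	62.9	155.8	158.0	164.1	115.5	172.9	194.1	92.9	85.6	106.5	224.6	177.7	141.0
Pt	Turn tendency	Secondary Structure		AAindex:CHOP780203	0.74	1.01	1.46	1.52	0.96	0.96	0.95	1.56	0.95	0.47	0.50	1.19	0.60	0.66	1.56	1.43	0.98	0.60	1.14	0.59
Ra	Solvent accessibility reduction ratio	Solvent Accessibility		AAindex:PONP800107	3.70	2.53	2.12	2.60	3.03	2.70	3.30	3.13	3.57	7.69	5.88	1.79	5.21	6.60	2.12	2.43	2.60	6.25	3.03	7.14
Na	Average number of surrounding residues	Tertiary Structure		AAindex:PONP800108	6.05	5.70	5.04	4.95	7.86	5.45	5.10	6.16	5.80	7.51	7.37	4.88	6.39	6.62	5.65	5.53	5.81	6.98	6.73	7.62
Br	Buriedness	Tertiary Structure		AAindex:WERD780101 (proxy)	0.52	0.49	0.42	0.37	0.83	0.35	0.38	0.41	0.70	0.79	0.77	0.31	0.76	0.87	0.35	0.49	0.38	0.86	0.64	0.72
K0	Compressibility	Tertiary Structure	m^3/mol/Pa x 10^-15	AAindex:KARP850101 (proxy)	1.041	1.038	1.117	1.033	0.960	1.165	1.094	1.142	0.982	1.002	0.967	1.093	0.947	0.930	1.055	1.169	1.073	0.925	0.961	0.982
F	Mean rms fluctuational displacement	Tertiary Structure	A	AAindex:VINM940101 (proxy)	0.984	1.008	1.048	1.068	0.906	1.037	1.094	1.031	0.950	0.927	0.935	1.102	0.952	0.915	1.049	1.046	0.997	0.904	0.929	0.931
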