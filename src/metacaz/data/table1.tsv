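ec	enzyme	substrate	Mn	Od	Cu	Aw	Nt	Th	Co	Mp	Nc
3.2.1.14	Chitinase	Chitin	209.59	33.14	3.38	16.89	5.97	8.74	14.70	39.06	43.58
3.2.1.52	β-N-Acetylhexosaminidase	Chitin	317.18	208.60	23.51	172.84	84.44	67.93	127.47	362.88	357.39
3.5.1.41	Chitin deacetylase	Chitin	1.79	5.46	2.09	16.89	8.71	3.38	11.30	24.00	4.98
3.2.1.132	Chitosanase	Chitin	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.165	Exo-β-glucosaminidase	Chitin	34.37	18.35	0.43	0.00	4.56	1.68	0.00	1.35	0.28
3.2.1.39	Endo-1,3-β-glucanase	β-Glucan	45.73	36.28	1.75	0.00	0.68	2.35	4.05	26.47	13.15
3.2.1.58	Exo-1,3-β-glucanase	β-Glucan	21.12	18.12	3.36	0.00	3.92	2.68	2.67	20.37	2.86
3.2.1.75	Endo-1,6-β-glucosidase	β-Glucan	48.53	16.34	0.61	6.14	3.96	3.17	0.00	1.34	0.00
3.2.1.21	Exo-β-glucosidase	β-Glucan	415.89	251.02	4.78	75.52	38.20	47.17	95.79	249.86	207.43
3.2.1.59	Endo-1,3-α-glucosidase	α-Glucan	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.84	Exo-1,3-α-glucanase	α-Glucan	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.20	Endo-1,4-α-glucanase	α-Glucan	6.59	21.58	2.27	0.00	2.40	1.67	0.35	0.57	27.73
3.2.1.3	Exo-1,4-α-glucanase	α-Glucan	19.64	16.52	1.25	0.00	0.30	0.00	0.00	1.02	0.31
3.2.1.4	Endo-1,4-β-glucanase	Cellulose	135.62	218.16	16.71	27.63	40.83	41.57	243.08	685.00	793.69
3.2.1.176	Cellobiohydrolase (reducing end)	Cellulose	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.91	Cellobiohydrolase (nonreducing end)	Cellulose	0.00	0.00	0.00	0.00	0.00	1.42	0.00	0.00	0.00
1.1.99.18	Cellobiose dehydrogenase	Cellulose	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
1.1.99.29	Pyranose dehydrogenase	Cellulose	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
LPMO	Lytic polysaccharide monooxygenase	Cellulose	0.00	0.00	0.18	0.00	0.00	0.00	0.00	0.00	1.11
3.2.1.8	Endo-1,4-β-xylanase	Hemicellulose	127.75	204.86	11.58	247.14	57.88	44.17	426.90	591.74	780.19
3.2.1.37	Exo-β-1,4-xylosidase	Hemicellulose	314.18	308.09	5.81	142.76	23.47	58.63	146.37	290.59	199.88
3.2.1.131	Xylan α-1,2-glucuronosidase	Hemicellulose	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.177	α-Xylosidase	Hemicellulose	167.41	158.69	4.18	19.96	8.43	40.55	30.39	75.39	59.00
3.2.1.151	Xyloglucan endo-β-1,4-glucanase	Hemicellulose	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.1.1.72	Acetyl xylan esterase	Hemicellulose	69.49	114.59	4.62	0.00	9.04	3.26	10.34	35.56	88.05
3.1.1.6	Acetylesterase	Hemicellulose	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.1.1.73	Feruloyl esterase	Hemicellulose	0.00	0.00	0.00	0.00	0.29	0.00	0.00	0.00	0.62
3.2.1.55	α-Arabinofuranosidase	Hemicellulose	184.50	211.25	9.03	27.02	28.15	48.96	57.67	175.31	138.77
3.2.1.99	Arabinan endo-α-1,5-arabinanase	Hemicellulose	31.75	20.05	0.77	0.00	6.81	2.73	1.78	0.60	0.15
1.10.3.2	Laccase	Lignin	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.25	5.63
3.1.1.-	4-O-Methyl-glucuronoyl methylesterase	Lignin	58.92	104.66	11.20	27.63	39.18	35.32	24.60	34.79	131.45
1.11.1.16	Versatile peroxidase	Lignin	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
4.2.2.2	Pectate lyase	Pectin	36.00	53.84	0.00	0.00	1.97	3.70	11.00	24.54	7.81
4.2.2.10	Pectin lyase	Pectin	0.72	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.1.1.-	Pectin acetyl esterase/rhamnogalacturonanacetylesterase	Pectin	106.96	80.44	6.96	39.91	12.42	9.49	2.25	11.76	25.42
3.1.1.11	Pectin methyl esterase	Pectin	72.57	56.74	0.00	0.00	0.28	1.12	5.31	0.94	0.00
3.2.1.15	Endopolygalacturonases	Pectin	92.05	61.05	0.30	38.68	8.83	6.42	11.63	20.46	20.44
3.2.1.67	Exopolygalacturonases	Pectin	0.00	0.92	0.00	0.00	1.22	0.64	0.00	0.71	0.00
3.2.1.174	Rhamnogalacturonan rhamnohydrolase	Pectin	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.40	α-Rhamnosidase	Pectin	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
3.2.1.-	Endo-1,2-α-mannanase	Mannan	91.35	92.10	8.77	0.00	29.61	24.99	15.19	34.57	34.26
3.2.1.24	Exo-α-mannosidase	Mannan	20.32	24.65	1.32	0.00	11.59	13.28	14.53	26.42	10.72
3.2.1.101	Endo-1,6-α-mannanase	Mannan	9.73	7.04	0.46	0.00	1.58	0.59	0.00	0.00	0.00
3.2.1.-	Exo-1,6-α-mannosidase	Mannan	39.84	34.46	1.13	0.00	1.07	2.10	0.14	1.14	1.95
3.2.1.78	Endo-1,4-β-mannanase	Mannan	48.81	48.74	11.00	43.29	17.61	15.77	44.69	117.11	109.08
3.2.1.25	β-Mannosidase	Mannan	31.94	21.11	1.16	0.00	12.34	24.07	12.09	45.02	36.08
3.2.1.22	Exo-α-galactosidase	Galactan	116.54	112.55	14.60	59.87	57.90	76.76	77.72	162.74	152.89
3.2.1.23	β-Galactosidase	Galactan	533.54	390.10	13.60	18.73	64.91	71.15	92.29	175.80	181.17
3.2.1.49	α-N-Acetylgalactosaminidase	Galactan	138.91	85.11	22.08	7.37	106.47	67.98	10.30	10.49	2.58
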