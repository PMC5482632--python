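gene	entrez_id	ars_ball	ars_bcell	delta	ars_ball_updated	ars_bcell_updated	delta_updated	ars_cll
DNTT	1791	97.30	45.25	52.05	99.00	47.28	51.72	42.39
C5orf62	85027	97.13	47.78	49.35	97.11	50.27	46.84	52.62
GNA15	2769	94.21	44.21	50.00	95.02	45.13	49.89	47.05
VPREB1	7441	93.07	30.73	62.34	89.57	33.17	56.40	25.72
CSRP2	1466	91.75	43.77	47.98	92.55	43.16	49.39	38.69
ERG	2078	90.97	36.54	54.43	92.32	34.78	57.54	35.76
FLT3	2322	90.64	37.59	53.05	91.01	38.50	52.51	56.06
IGFBP7	3490	90.24	35.91	54.33	88.47	33.91	54.56	44.68
HBEGF	1839	89.86	39.48	50.38	90.75	41.42	49.33	42.88
SPRY2	10253	89.27	38.67	50.60	89.73	33.85	55.88	60.34
RASD1	51655	89.25	41.85	47.40	92.93	40.56	52.37	52.62
CPNE2	221184	89.24	37.13	52.11	89.45	37.14	52.31	40.25
ZNF423	23090	87.66	23.05	64.61	86.55	22.73	63.82	20.50
FRMD4B	23150	87.47	28.57	58.90	89.47	27.75	61.72	36.59
DBN1	1627	85.85	37.34	48.51	87.18	38.32	48.86	48.35
CLEC11A	6320	85.67	36.54	49.13	87.63	41.00	46.63	29.93
C19orf77	284422	84.80	30.51	54.29	84.85	34.01	50.84	28.16
SLC22A16	85413	84.63	28.30	56.33	85.99	27.33	58.66	30.61
CTGF	1490	83.18	31.71	51.47	83.32	36.01	47.31	14.16
COL5A1	1289	81.38	31.69	49.69	85.45	36.79	48.66	29.17
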