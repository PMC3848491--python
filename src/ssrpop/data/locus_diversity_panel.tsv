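locus	n	Ao	Ae	Ho	He	F	PD	MAF	Gn
UDP96-018	653	12	2.33	0.42	0.55	0.25	0.73	0.63	23
CPPCT027	653	11	2.32	0.46	0.50	0.08	0.68	0.68	22
EPPCU1090	653	7	2.70	0.53	0.59	0.10	0.79	0.59	14
UDP96-005	653	15	4.31	0.63	0.73	0.14	0.88	0.41	41
CPPCT026	653	21	5.01	0.61	0.78	0.23	0.90	0.37	56
BPPCT020	653	10	2.59	0.49	0.65	0.24	0.81	0.43	16
CPPCT029	653	13	2.27	0.45	0.61	0.26	0.77	0.50	34
CPPCT044	653	13	4.30	0.52	0.76	0.31	0.89	0.41	39
CPPCT042	653	15	2.19	0.41	0.64	0.36	0.80	0.50	33
BPPCT001	653	14	3.11	0.51	0.79	0.35	0.90	0.36	47
BPPCT024	653	10	5.52	0.49	0.75	0.35	0.85	0.42	28
UDP96-013	653	14	3.73	0.50	0.76	0.34	0.88	0.31	31
pceGA34	653	9	2.05	0.41	0.55	0.26	0.72	0.51	16
pchgms1	653	6	1.71	0.23	0.31	0.26	0.46	0.81	7
UDP98-025	653	8	2.87	0.47	0.75	0.38	0.88	0.35	21
BPPCT007	653	11	4.34	0.63	0.73	0.15	0.88	0.43	33
BPPCT039	653	7	1.61	0.41	0.39	-0.05	0.57	0.75	11
CPPCT002	653	8	2.37	0.42	0.59	0.28	0.74	0.46	14
UDP96-008	653	8	2.82	0.47	0.61	0.23	0.79	0.52	18
UDP96-003	653	15	2.99	0.61	0.66	0.08	0.80	0.43	40
UDP98-024	653	11	2.56	0.56	0.63	0.12	0.81	0.43	19
PTS1-SSR	429	10	3.95	0.61	0.75	0.18	0.89	0.34	21
CPPCT005	653	15	2.31	0.48	0.61	0.21	0.79	0.54	26
BPPCT015	653	20	2.82	0.55	0.66	0.17	0.81	0.46	43
CPPCT046	653	12	2.69	0.44	0.62	0.29	0.78	0.45	22
CPPCT040	653	12	2.68	0.58	0.63	0.07	0.76	0.51	25
EPPCU1775	429	13	3.68	0.51	0.73	0.30	0.75	0.39	26
UDP97-401	653	11	2.25	0.45	0.52	0.14	0.67	0.58	16
BPPCT017	653	16	3.95	0.58	0.71	0.18	0.86	0.38	44
BPPCT037	653	16	1.92	0.49	0.50	0.02	0.66	0.66	25
BPPCT038	653	13	3.28	0.52	0.69	0.24	0.83	0.48	40
BPPCT014	653	11	1.55	0.28	0.36	0.21	0.50	0.79	16
CPPCT013	653	6	1.64	0.28	0.29	0.05	0.46	0.83	11
CPSCT006	653	10	2.05	0.40	0.42	0.05	0.61	0.74	20
CPPCT015	653	13	1.46	0.16	0.23	0.34	0.34	0.87	30
BPPCT025	653	16	5.54	0.62	0.81	0.24	0.94	0.30	56
pchcms5	653	10	2.41	0.46	0.53	0.13	0.72	0.64	20
UDP96-001	653	13	4.04	0.51	0.68	0.26	0.84	0.50	30
CPPCT022	653	24	3.77	0.59	0.78	0.25	0.92	0.35	58
CPPCT030	653	14	2.28	0.56	0.60	0.07	0.79	0.58	34
CPPCT033	653	9	1.84	0.24	0.56	0.57	0.68	0.58	19
PMS02	653	12	1.23	0.13	0.17	0.23	0.28	0.91	22
pchgms6	653	14	3.17	0.49	0.70	0.30	0.86	0.42	35
BPPCT006	653	15	6.97	0.63	0.85	0.26	0.95	0.26	65
UDP98-409	653	13	2.80	0.49	0.60	0.19	0.77	0.57	24
CPPCT006	653	10	2.25	0.49	0.63	0.23	0.79	0.49	15
PCeGA25	429	8	1.61	0.36	0.38	0.06	0.54	0.76	13
Pchgms3	653	14	2.88	0.48	0.57	0.17	0.74	0.61	29
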