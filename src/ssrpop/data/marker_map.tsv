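locus	linkage_group	cm	scaffold	bp
UDP96-018	1	1	scaffold_1	1299253
CPPCT027	1	23.1	scaffold_1	12409317
UDP96-005	1	29.2	scaffold_1	13903361
EPPCU1090	1	32	scaffold_1	22653855
CPPCT026	1	33.9	scaffold_1	31792505
Pchgms3	1	37.5	scaffold_1	27692065
BPPCT020	1	52.6	scaffold_1	33281268
CPPCT042	1	62.5	scaffold_1	39307938
CPPCT029	1	65.1	scaffold_1	40195426
CPPCT044	2	7.2	scaffold_2	10280697
UDP98-025	2	9.6	scaffold_2	10872102
BPPCT001	2	20.9	scaffold_2	16134154
UDP96-013	2	27.8	scaffold_2	18895940
pchgms1	2	35.1	scaffold_2	21255607
BPPCT024	2	36.3	scaffold_2	22674207
pceGA34	2	43.9	scaffold_2	25199147
BPPCT007	3	11.2	scaffold_3	2741939
BPPCT039	3	18	scaffold_3	5802709
CPPCT002	3	31.9	scaffold_3	16205250
UDP96-008	3	36.4	scaffold_3	16946762
PTS1-SSR	4	5.2	scaffold_4	1414471
UDP98-024	4	11.3	scaffold_4	3499623
CPPCT005	4	10.4	scaffold_4	10269880
UDP96-003	4	28.3	scaffold_4	8757450
BPPCT015	4	44	scaffold_4	12546880
CPPCT046	4	45.4	scaffold_4	14476745
EPPCU1775	4	52	scaffold_4	22684553
CPPCT040	5	1.5	scaffold_5	993617
UDP97-401	5	11	scaffold_5	5940392
BPPCT017	5	20.1	scaffold_5	11174442
BPPCT037	5	25.6	scaffold_5	12312049
BPPCT038	5	32.9	scaffold_5	14658198
PCeGA25	5	28.4	scaffold_5	12835942
CPPCT013	5	29.2	scaffold_5	12835904
CPSCT006	5	21.7	scaffold_5	11533644
BPPCT014	5	44	scaffold_5	16626108
UDP96-001	6	17.5	scaffold_6	7040757
CPPCT015	6	35.8	scaffold_6	16352480
pchcms5	6	44.7	scaffold_6	19166654
BPPCT025	6	56.4	scaffold_6	21129947
CPPCT030	6	80.2	scaffold_6	26851012
CPPCT022	7	18.6	scaffold_7	10225365
pchgms6	7	19.4	scaffold_7	10439493
CPPCT033	7	38.9	scaffold_7	16702195
PMS02	7	47.8	scaffold_7	18106236
BPPCT006	8	14.1	scaffold_8	5982783
CPPCT006	8	24.8	scaffold_8	13659021
UDP98-409	8	44.5	scaffold_8	17783528
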