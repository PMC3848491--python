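subpopulation	sample_size	n_comparisons	inter_chromosome	pct_inter_r2_gt_0.1	intra_chromosome	pct_intra_r2_gt_0.1
Oriental	234	3148	2695	6	453	17
Hakuho	161	2774	2379	6	395	20
Yu Lu	34	1851	1566	36	285	47
Occidental	174	2435	2102	4	333	14
Nectarine	69	2434	2139	5	295	17
Peach	52	2437	2092	20	345	29
Landraces	61	5122	4317	7	805	7
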