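line	n_cells	chromatid_gaps	chromatid_breaks	isochromatid_gaps	isochromatid_breaks
wild-type	100	0	1	1	0
polz	100	0	2	2	8
polh	100	1	0	0	0
polh_polz	100	0	0	0	2
polh_polz_wt_Polh	100	0	6	1	7
polh_polz_mut_Polh	100	0	2	2	0
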