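bin_name	full_name	arm	frac_start	frac_end	n_markers	size_mb	map_cR	map_cM
3BS3	3BS3-0.87-1.00	S	0.87	1.00	7	56.0	79.7	5.2
3BS8	3BS8-0.78-0.87	S	0.78	0.87	155	39.0	572.9	33.1
3BS9	3BS9-0.57-0.75	S	0.57	0.75	9	78.0	69.2	13.4
3BS2	3BS2-0.56-0.57	S	0.56	0.57	3	4.0	36.7	NA
3BS1	3BS1-0.33-0.55	S	0.33	0.55	44	95.0	113.7	1.6
C-3BS1	C-3BS1-0.33	S	0.00	0.33	28	142.0	115.6	0.9
C-3BL2	C-3BL2-0.22	L	0.00	0.22	27	124.0	99.1	1.6
3BL2	3BL2-0.22-0.28	L	0.22	0.28	29	33.0	58.9	1.6
3BL1	3BL1-0.31-0.50	L	0.31	0.50	47	39.0	37.0	6.2
3BL10	3BL10-0.50-0.63	L	0.50	0.63	4	73.0	41.3	3.5
3BL7	3BL7-0.63-1.00	L	0.63	1.00	187	208.0	459.6	104.2
Chr	Chr	NA	NA	NA	540	992.0	1871.9	179.0
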