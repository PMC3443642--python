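contig_id	size_mb	span_cR	n_markers	bin_name
Ctg0954	2.6	311.5	12	3BS8
Ctg0209	0.2	4.2	3	3BS1
Ctg0255	0.6	13.8	2	3BS1
Ctg1017	0.9	8.8	2	3BS1
Ctg0005	3.0	37.0	6	3BL1
Ctg0235	0.4	18.3	3	3BL7
Ctg0464	1.9	9.1	3	3BL7
Ctg0012	1.2	4.5	2	3BL7
Ctg0157	0.3	2.0	2	3BL7
Ctg0273	0.3	0.0	2	3BL2
Ctg1033	0.1	0.0	2	3BL2
Ctg0145	0.0	0.0	3	3BL7
Ctg0152	0.2	0.0	3	3BL7
Ctg0436	0.2	0.0	2	3BL7
Ctg0532	0.2	0.0	2	3BL7
Ctg0653	0.4	0.0	2	3BL7
Ctg0694	0.1	0.0	2	3BL7
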