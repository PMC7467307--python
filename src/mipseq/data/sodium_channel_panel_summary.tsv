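gene	mip_bp	tsca_bp	mip_probes	tsca_probes	mip_pct_gt30	tsca_pct_gt30	mip_failed	tsca_failed
SCN3A	7043	7175	55	33	99.6	99.3	0	0
SCN8A	6943	6983	49	33	97.6	97.1	0	2
SCN9A	6934	6974	49	32	98.7	95.8	0	1
SCN10A	6871	6951	43	34	99.9	98.6	0	0
SCN11A	6379	6416	46	32	99.9	91.6	1	1
SCN1B	967	1216	13	6	93.6	91.3	1	1
SCN2B	768	808	6	5	100.0	93.2	0	0
SCN3B	808	848	6	5	100.0	98.7	0	0
SCN4B	754	887	9	5	86.5	79.7	1	1
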