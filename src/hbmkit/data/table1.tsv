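id	age	ls_z	hip_z	sum_z	cohort	dna_available	genotyped
HBM1	51	3.4	2.7	6.1	BARCOS	0	0
HBM2	57	3.0	1.6	4.6	BARCOS	1	1
HBM3	55	2.5	2.4	4.9	BARCOS	1	1
HBM4	62	2.5	2.0	4.5	BARCOS	1	1
HBM5	66	2.4	2.1	4.5	BARCOS	1	1
HBM6	52	2.6	2.5	5.1	BARCOS	1	1
HBM7	61	2.5	2.1	4.6	BARCOS	1	1
HBM8	55	4.0	3.9	7.9	BARCOS	0	0
HBM9	66	4.6	2.4	7.0	BARCOS	1	1
HBM10	75	2.8	2.3	5.1	BARCOS	1	1
HBM11	55	3.8	3.0	6.8	HSANTPAU	0	0
HBM12	59	3.8	2.6	6.4	CETIR	1	1
HBM13	67	2.6	2.6	5.2	CETIR	1	1
HBM14	64	3.7	2.3	6.0	CETIR	1	0
HBM15	54	2.4	2.1	4.5	CETIR	1	1
HBM16	77	3.6	1.7	5.3	HESP	1	0
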