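id	relation	sum_z	carrier
HBM15	proband	4.5	carrier
daughter	offspring	4.9	carrier
son	offspring	0.5	non-carrier
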