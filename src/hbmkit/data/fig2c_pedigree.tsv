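id	relation	sum_z	carrier
HBM9	proband	7.0	unknown
mother	parent	4.4	unknown
eldest_brother	sibling	NA	unknown
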