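line_id	gene_symbol	role
shCTL	CTL	control
shCSNK2A1	CSNK2A1	targeted
shCDK4	CDK4	targeted
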