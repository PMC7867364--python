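line_id	gene_symbol	compound_id	concentration_uM	kill_compound	kill_knockdown	kill_interaction	kill_total
shCTL	CTL	CPD001	20.0	0.20785889994156365	0.0	0.0	0.2078588999415636
shCTL	CTL	CPD020	20.0	0.2693355172166791	0.0	0.0	0.26933551721667914
shCTL	CTL	CPD023	20.0	0.10765573373851657	0.0	0.0	0.10765573373851656
shCSNK2A1	CSNK2A1	CPD001	20.0	0.20785889994156365	0.01463013449756801	0.0	0.21944803077647002
shCSNK2A1	CSNK2A1	CPD020	20.0	0.2693355172166791	0.01463013449756801	0.0	0.2800252368723951
shCSNK2A1	CSNK2A1	CPD023	20.0	0.10765573373851657	0.01463013449756801	0.3	0.42071085037205563
shCDK4	CDK4	CPD001	20.0	0.20785889994156365	0.012281329137948405	0.0	0.2175874455150778
shCDK4	CDK4	CPD020	20.0	0.2693355172166791	0.012281329137948405	0.0	0.2783090482191499
shCDK4	CDK4	CPD023	20.0	0.10765573373851657	0.012281329137948405	0.0	0.11861490737683489
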