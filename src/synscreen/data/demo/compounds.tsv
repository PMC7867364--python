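compound_id	name	target_annotation	fda_approved
CPD001	sunitinib	VEGFR/PDGFR/KIT	1
CPD020	palbociclib	CDK4/6	1
CPD023	KU-60019	ATM	0
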