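IFNG_production	IFN-gamma effector program	TBX21	EOMES	STAT1	STAT4	IL12RB	IFNG
IL17_production	IL17A effector program	RORC	IL23R	CCR6	IL1R1	RORA	BLK	IL17A
cytotoxicity	cytotoxic effector program	GZMA	GZMB	GZMK	GZMM	GZMH	PRF1	TRAIL	FAS	IL12
antigen_presentation	MHC class II antigen presentation	HLA-DQPB1	HLA-DRA	HLA-DPA1
innate	innate activating receptor program	KLRK1	HCST
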