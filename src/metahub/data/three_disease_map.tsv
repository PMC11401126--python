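source	target	effect	disease
CD44	AKT1	activate	3D
EGFR	AKT1	activate	3D
AKT1	NFKB1	activate	3D
AKT1	STAT3	activate	3D
AKT1	MMP9	activate	3D
NFKB1	MMP9	activate	3D
STAT3	MMP1	activate	3D
CTNNB1	MMP1	activate	3D
CTNNB1	MMP9	activate	3D
#node	IFNG
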