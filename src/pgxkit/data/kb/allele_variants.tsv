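gene	allele	rsid	required_state
CYP2C19	*2	rsV2	A
CYP2C19	*8	rsV8	C
CYP2C19	*17	rsV17	T
CYP2C19	*6	rsV6	A
CYP2C9	*2	rsW2	T
CYP2C9	*3	rsW3	C
CYP2C9	*14	rsW14	A
CYP2D6	*3	rsD3	G
CYP2D6	*4	rsD4	A
CYP2D6	*5	rsD5	T
CYP2D6	*6	rsD6	C
CYP2D6	*7	rsD7	C
CYP2D6	*9	rsD9	G
CYP2D6	*10	rsD10	T
CYP2D6	*41	rsD41	A
CYP2D6	*36	rsD36	C
TPMT	*2	rsT2	C
TPMT	*3A	rsT460	A
TPMT	*3A	rsT719	G
TPMT	*3B	rsT460	A
SLCO1B1	V174A	rsS174	C
SLCO1B1	*6	rsS6	A
SLCO1B1	*3	rsS3	G
VKORC1	A	rs9923231	A
CYP4F2	A	rsV433M	A
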