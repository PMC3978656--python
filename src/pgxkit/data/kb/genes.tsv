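gene	reference_allele
CYP2C19	*1
CYP2C9	*1
CYP2D6	*1
TPMT	*1
SLCO1B1	*1
VKORC1	G
CYP4F2	G
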