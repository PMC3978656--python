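gene	name	function_class	activity_value	similarity_reference
CYP2C19	*1	normal	1.0
CYP2C19	*2	none	0
CYP2C19	*8	none	0
CYP2C19	*17	increased	1.5
CYP2C19	*6	none	0	*2
CYP2C9	*1	normal	1.0
CYP2C9	*2	reduced	0.5
CYP2C9	*3	none	0
CYP2C9	*14	reduced	0.5
CYP2D6	*1	normal	1.0
CYP2D6	*3	none	0
CYP2D6	*4	none	0
CYP2D6	*5	none	0
CYP2D6	*6	none	0
CYP2D6	*7	none	0
CYP2D6	*9	reduced	0.5
CYP2D6	*10	reduced	0.25
CYP2D6	*41	reduced	0.5
CYP2D6	*36	none	0
TPMT	*1	normal	1.0
TPMT	*2	none	0
TPMT	*3A	none	0
TPMT	*3B	none	0
SLCO1B1	*1	normal	1.0
SLCO1B1	V174A	reduced	0.5
SLCO1B1	*6	reduced	0.5
SLCO1B1	*3	reduced	0.5
VKORC1	G	normal	1.0
VKORC1	A	reduced	0.5
CYP4F2	G	normal	1.0
CYP4F2	A	reduced	0.5
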