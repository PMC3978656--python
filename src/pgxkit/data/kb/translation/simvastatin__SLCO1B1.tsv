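category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
NORMAL	normal_transport		Normal response and risk of adverse drug reactions to simvastatin; normal drug transport	80 mg simvastatin maximum dose	*1/*1	64	92	79
INT_DEC	decreased_transport		Intermediate increase in risk of myopathy from simvastatin; intermediate decreased drug transport	40 mg simvastatin maximum dose	*1/V174A;*1/*6;*1/*3	32	8	20
DEC	decreased_transport		Increased risk of myopathy from simvastatin; decreased drug transport	20 mg simvastatin maximum dose	V174A/V174A;*6/V174A	4	<1	1
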