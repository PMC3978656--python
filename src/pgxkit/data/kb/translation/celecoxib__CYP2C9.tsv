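category_id	pkpd_label	policy_function	clinical_text	fda_text	member_diplotypes	freq_caucasian	freq_african	freq_eastasian
EM	EM		Expected to have a normal analgesic response at standard dose of celecoxib. Colorectal adenoma treatment: no additional efficacy with 400 mg twice daily compared with 200 mg twice daily		*1/*1	67	84.5	92
IM	IM		Insufficient data; predicted risk of side effects is unknown. Likely reduced enzymatic function and drug elimination, leading to increased drug exposure		*1/*2;*1/*3	30	15	8
PM	PM		Greater risk of adverse cardiovascular events with 400 mg celecoxib twice daily. Colorectal adenoma treatment: decreased recurrence with 400 mg twice daily	Consider 50% of the standard starting dose in PMs; consider alternative treatment in PMs with juvenile rheumatoid arthritis	*3/*3;*2/*3;*2/*2	3	0.6	0.2
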